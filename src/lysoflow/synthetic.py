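"""Synthetic observations with the statistical structure the analysis
assumes, plus parameter-recovery utilities.

Three kinds of measurements are emulated:

* **lysosome radii** — lognormal around the measured population means
  (379 nm in untreated macrophages, 439 nm after nanomotor uptake); the
  dispersion of the real distributions is unpublished, so the default CV
  of 0.25 is a placeholder;
* **viscometry readings** — Förster–Hoffmann power-law intensities with
  multiplicative lognormal noise, the typical noise family for
  fluorescence;
* **chain counts versus frequency** — the assembly model's equilibrium
  particle number with rounded-lognormal counting noise, emulating
  electron-microscopy counts of assembled nanomotors.

The default chain-count frequency sweep is placed in the cohesion-limited
regime of the assembly model (hundreds of Hz for the default particle),
where the observed counts actually carry information about the dipolar
bond strength; at video-rate actuation frequencies (0.2-5 Hz) the
geometric confinement cap saturates the counts and the bond strength is
unidentifiable — :func:`recover_bond_strength` raises in that case.

Every sampler takes its randomness from ``numpy.random.default_rng`` seeded
with ``SyntheticConfig.seed``; identical configurations produce identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import IdentifiabilityError, InvalidParameterError
from .geometry import MEAN_RADIUS_UNTREATED, LysosomeGeometry
from .magnetics import (
    AssemblyCriteria,
    Nanoparticle,
    RotatingField,
    equilibrium_chain,
)
from .viscometry import fit_calibration

__all__ = [
    "SyntheticConfig",
    "sample_lysosome_radii",
    "simulate_viscometry",
    "simulate_chain_counts",
    "recover_bond_strength",
    "BondStrengthEstimate",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of all synthetic samplers (single shared seed)."""

    seed: int = 0
    n_lysosomes: int = 10_000
    radius_mean: float = MEAN_RADIUS_UNTREATED
    radius_cv: float = 0.25
    viscometry_noise_cv: float = 0.10
    chain_count_noise: float = 0.15
    frequencies: tuple[float, ...] = (180.0, 240.0, 300.0, 360.0)
    n_obs_per_frequency: int = 50

    def __post_init__(self):
        if int(self.seed) != self.seed:
            raise InvalidParameterError("seed must be an integer")
        for name in ("radius_cv", "viscometry_noise_cv", "chain_count_noise"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.n_lysosomes < 1 or self.n_obs_per_frequency < 1:
            raise InvalidParameterError("sample sizes must be >= 1")
        if not (self.radius_mean > 0):
            raise InvalidParameterError("radius_mean must be > 0")
        if any(f <= 0 for f in self.frequencies):
            raise InvalidParameterError("frequencies must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(int(self.seed))


def _lognormal_mean_cv(
    rng: np.random.Generator, mean: float, cv: float, size
) -> np.ndarray:
    """Lognormal draws parameterised by arithmetic mean and CV; the
    degenerate cv = 0 returns the mean exactly."""
    if cv == 0.0:
        return np.full(size, mean, dtype=float)
    sigma2 = math.log1p(cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def sample_lysosome_radii(cfg: SyntheticConfig) -> np.ndarray:
    """Lognormal lysosome radii (m) with the configured mean and CV."""
    return _lognormal_mean_cv(cfg.rng(), cfg.radius_mean, cfg.radius_cv, cfg.n_lysosomes)


def simulate_viscometry(
    cfg: SyntheticConfig,
    true_exponent: float,
    true_prefactor: float,
    viscosities_cp,
) -> pd.DataFrame:
    """Noisy calibration points ``I = k eta^x * lognormal(cv)``.

    Returns a DataFrame with columns ``viscosity_cp`` and ``intensity``
    suitable for :func:`lysoflow.viscometry.fit_calibration`.
    """
    if true_exponent <= 0 or true_prefactor <= 0:
        raise InvalidParameterError("true exponent and prefactor must be > 0")
    eta = np.asarray(list(viscosities_cp), dtype=float)
    if np.any(eta <= 0):
        raise InvalidParameterError("viscosities must be > 0")
    ideal = true_prefactor * eta**true_exponent
    noise = _lognormal_mean_cv(cfg.rng(), 1.0, cfg.viscometry_noise_cv, len(eta))
    return pd.DataFrame({"viscosity_cp": eta, "intensity": ideal * noise})


def simulate_chain_counts(
    cfg: SyntheticConfig,
    particle: Nanoparticle,
    criteria: AssemblyCriteria,
    field: RotatingField,
    lysosome: LysosomeGeometry,
) -> pd.DataFrame:
    """Observed assembled-particle counts per frequency.

    The true count is the assembly model's equilibrium ``n_particles``;
    observations add rounded multiplicative lognormal noise (dispersion
    ``chain_count_noise``), truncated below at one particle.  Columns:
    ``frequency_hz``, ``observed_n``, ``true_n``.
    """
    rng = cfg.rng()
    rows = []
    for f in cfg.frequencies:
        field_f = RotatingField(field.amplitude, float(f), field.duration)
        n_true = equilibrium_chain(particle, criteria, field_f, lysosome).n_particles
        noisy = n_true * _lognormal_mean_cv(
            rng, 1.0, cfg.chain_count_noise, cfg.n_obs_per_frequency
        )
        observed = np.maximum(1, np.rint(noisy).astype(int))
        for obs in observed:
            rows.append(
                {"frequency_hz": float(f), "observed_n": int(obs), "true_n": n_true}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BondStrengthEstimate:
    """Grid-search estimate of ``bond_strength_scale``.

    The squared-log-count loss is piecewise constant in the bond strength
    (counts are integers), so the minimiser is an interval; ``estimate`` is
    its geometric midpoint and ``uncertainty`` its half-width.
    """

    estimate: float
    uncertainty: float
    interval: tuple[float, float]
    loss: float


def recover_bond_strength(
    observations: pd.DataFrame,
    particle: Nanoparticle,
    field: RotatingField,
    lysosome: LysosomeGeometry,
    criteria: AssemblyCriteria | None = None,
    grid: np.ndarray | None = None,
) -> BondStrengthEstimate:
    """Invert chain-count observations for the dipolar bond-strength scale.

    Minimises ``sum_i (ln n_obs_i - ln n_pred(f_i; kappa))^2`` over a
    logarithmic grid of candidate scales.  Raises
    :class:`IdentifiabilityError` when the predictions do not depend on the
    candidate scale anywhere on the grid (all counts capped by geometry or
    step-out, so the data carry no bond-strength signal).
    """
    if criteria is None:
        criteria = AssemblyCriteria()
    if grid is None:
        grid = np.geomspace(0.2, 5.0, 801)
    freqs = np.sort(observations["frequency_hz"].unique())
    if len(freqs) < 3:
        raise InvalidParameterError(
            "need observations at >= 3 distinct frequencies"
        )
    preds = np.empty((len(grid), len(freqs)), dtype=int)
    for j, f in enumerate(freqs):
        field_f = RotatingField(field.amplitude, float(f), field.duration)
        for i, kappa in enumerate(grid):
            crit = replace(criteria, bond_strength_scale=float(kappa))
            preds[i, j] = equilibrium_chain(
                particle, crit, field_f, lysosome
            ).n_particles
    if np.all(preds == preds[0]):
        raise IdentifiabilityError(
            "chain counts are insensitive to the bond strength over the "
            "search grid: all observations sit on geometry or step-out caps"
        )
    log_obs = np.log(observations["observed_n"].to_numpy(dtype=float))
    freq_idx = np.searchsorted(freqs, observations["frequency_hz"].to_numpy())
    losses = (
        (np.log(preds[:, freq_idx]) - log_obs[None, :]) ** 2
    ).sum(axis=1)
    best = losses.min()
    in_argmin = losses <= best * (1.0 + 1e-12)
    kappas = grid[in_argmin]
    lo, hi = float(kappas.min()), float(kappas.max())
    estimate = math.sqrt(lo * hi)
    return BondStrengthEstimate(
        estimate=estimate,
        uncertainty=(hi - lo) / 2.0,
        interval=(lo, hi),
        loss=float(best),
    )


def viscometry_recovery_check(
    cfg: SyntheticConfig,
    true_exponent: float = 1.077,
    true_prefactor: float = 0.0187,
    n_points: int = 50,
) -> tuple[float, float, float]:
    """One viscometry round trip: simulate ``n_points`` noisy calibration
    points log-spaced across 10-1000 cP, refit, and return
    ``(fitted exponent, stderr, true exponent)``."""
    eta = np.geomspace(10.0, 1000.0, n_points)
    pts = simulate_viscometry(cfg, true_exponent, true_prefactor, eta)
    cal = fit_calibration(pts[["viscosity_cp", "intensity"]].to_numpy())
    return cal.exponent, cal.exponent_stderr, true_exponent
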