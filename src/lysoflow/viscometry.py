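"""Molecular-rotor (DCVJ) viscometry.

DCVJ is a fluorescent molecular rotor whose quantum yield rises with
solvent viscosity.  Over the calibration range the intensity follows the
Förster–Hoffmann power law ``I = k * eta^x``; fitting ``log I`` against
``log eta`` by ordinary least squares gives the exponent ``x`` and the
prefactor ``k`` (intensity at 1 cP), after which a fluorescence reading is
inverted to a viscosity estimate ``eta = (I / k)^(1/x)``.

Viscosities are handled in centipoise throughout this module because that
is the unit calibration standards are labelled in (1 cP = 1e-3 Pa s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import InvalidParameterError

#: The two-point calibration anchor: a 12-fold intensity increase between
#: 40 cP and 402 cP, the reference measurement for lysosomal fluid.
ANCHOR_POINTS = ((40.0, 1.0), (402.0, 12.0))


@dataclass(frozen=True)
class ViscosityCalibration:
    """Fitted Förster–Hoffmann calibration ``I = prefactor * eta^exponent``.

    ``calibration_range`` is the (min, max) viscosity in cP spanned by the
    calibration points; conversions outside it are flagged as
    extrapolations.  ``exponent_stderr`` is the OLS standard error of the
    exponent (0 for a two-point fit).
    """

    exponent: float
    prefactor: float
    fit_r_squared: float
    calibration_range: tuple[float, float]
    exponent_stderr: float = 0.0
    n_points: int = 2

    def __post_init__(self):
        if not (self.exponent > 0):
            raise InvalidParameterError("exponent must be > 0")
        if not (self.prefactor > 0):
            raise InvalidParameterError("prefactor must be > 0")
        lo, hi = self.calibration_range
        if not (lo < hi):
            raise InvalidParameterError("calibration_range must satisfy min < max")

    def intensity(self, viscosity_cp) -> np.ndarray:
        """Forward model: expected intensity at the given viscosity (cP)."""
        return self.prefactor * np.asarray(viscosity_cp, dtype=float) ** self.exponent


def fit_calibration(points: Iterable[Sequence[float]]) -> ViscosityCalibration:
    """Least-squares power-law fit of (viscosity cP, intensity) pairs.

    The fit is a straight line in (log eta, log I) — the natural space for
    the multiplicative noise of fluorescence readings.  With exactly two
    points the fit is exact (r^2 = 1).

    >>> cal = fit_calibration(ANCHOR_POINTS)
    >>> round(cal.exponent, 3)
    1.077
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise InvalidParameterError(
            "need at least two (viscosity, intensity) pairs"
        )
    eta, inten = pts[:, 0], pts[:, 1]
    if np.any(eta <= 0) or np.any(inten <= 0):
        raise InvalidParameterError("viscosities and intensities must be > 0")
    if len(np.unique(eta)) < 2:
        raise InvalidParameterError(
            "calibration requires at least two distinct viscosities"
        )
    res = stats.linregress(np.log(eta), np.log(inten))
    exponent = float(res.slope)
    if exponent <= 0:
        raise InvalidParameterError(
            f"fitted exponent {exponent:g} is not positive: intensities do "
            "not increase with viscosity"
        )
    r2 = float(res.rvalue**2)
    stderr = float(res.stderr) if len(pts) > 2 else 0.0
    return ViscosityCalibration(
        exponent=exponent,
        prefactor=float(math.exp(res.intercept)),
        fit_r_squared=r2,
        calibration_range=(float(eta.min()), float(eta.max())),
        exponent_stderr=stderr,
        n_points=len(pts),
    )


def intensity_to_viscosity(
    cal: ViscosityCalibration, intensity: float
) -> tuple[float, bool]:
    """Invert a fluorescence reading to viscosity (cP).

    Returns ``(viscosity_cp, extrapolated)`` where the flag is set when the
    result lies outside the calibration range.
    """
    if not (intensity > 0):
        raise InvalidParameterError("intensity must be > 0")
    eta = (intensity / cal.prefactor) ** (1.0 / cal.exponent)
    lo, hi = cal.calibration_range
    return float(eta), bool(eta < lo or eta > hi)
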