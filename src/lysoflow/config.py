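"""Run configuration: validated TOML loading and resolved-config output.

The configuration file mirrors the units the quantities are usually
reported in experimentally (nm, emu/g, mT, cP); the accessors convert to
SI objects.  Unknown keys are rejected so a typo cannot silently fall back
to a default.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Sequence

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import InvalidParameterError
from .geometry import LysosomeGeometry
from .magnetics import AssemblyCriteria, Nanoparticle, RotatingField
from .regime import RegimeThresholds
from .synthetic import SyntheticConfig

__all__ = ["RunConfig", "load_config", "dump_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class NanoparticleSection(_Section):
    edge_length_nm: float = 25.0
    saturation_magnetization_emu_g: float = 69.0
    mass_density_kg_m3: float = 5180.0
    coating_thickness_nm: float = 0.0

    def to_particle(self) -> Nanoparticle:
        return Nanoparticle(
            edge_length=self.edge_length_nm * 1e-9,
            saturation_magnetization=self.saturation_magnetization_emu_g,
            mass_density=self.mass_density_kg_m3,
            coating_thickness=self.coating_thickness_nm * 1e-9,
        )


class FieldSection(_Section):
    amplitude_mt: float = 260.0
    frequencies_hz: tuple[float, ...] = (0.2, 0.8, 1.0, 2.0, 5.0)

    def to_field(self, frequency: float | None = None) -> RotatingField:
        f = self.frequencies_hz[0] if frequency is None else frequency
        return RotatingField(amplitude=self.amplitude_mt * 1e-3, frequency=f)


class LysosomeSection(_Section):
    radius_nm: float = 359.2
    viscosity_cp: float = 471.1

    def to_lysosome(self) -> LysosomeGeometry:
        return LysosomeGeometry(
            radius=self.radius_nm * 1e-9, viscosity=self.viscosity_cp * 1e-3
        )


class AssemblySection(_Section):
    bond_strength_scale: float = 1.0
    geometric_fill_fraction: float = 0.7

    def to_criteria(self) -> AssemblyCriteria:
        return AssemblyCriteria(
            bond_strength_scale=self.bond_strength_scale,
            geometric_fill_fraction=self.geometric_fill_fraction,
        )


class ThresholdSection(_Section):
    """Explicit regime thresholds; when absent they are calibrated from
    the reference spectrum at run time."""

    tau_low_pa: float
    tau_high_pa: float

    def to_thresholds(self) -> RegimeThresholds:
        return RegimeThresholds(self.tau_low_pa, self.tau_high_pa)


class SolverSection(_Section):
    resolution: float = Field(default=1.0, gt=0.0)


class SyntheticSection(_Section):
    n_lysosomes: int = 10_000
    radius_mean_nm: float = 379.0
    radius_cv: float = 0.25
    viscometry_noise_cv: float = 0.10
    chain_count_noise: float = 0.15
    frequencies_hz: tuple[float, ...] = (180.0, 240.0, 300.0, 360.0)
    n_obs_per_frequency: int = 50

    def to_synthetic(self, seed: int) -> SyntheticConfig:
        return SyntheticConfig(
            seed=seed,
            n_lysosomes=self.n_lysosomes,
            radius_mean=self.radius_mean_nm * 1e-9,
            radius_cv=self.radius_cv,
            viscometry_noise_cv=self.viscometry_noise_cv,
            chain_count_noise=self.chain_count_noise,
            frequencies=self.frequencies_hz,
            n_obs_per_frequency=self.n_obs_per_frequency,
        )


class RunConfig(_Section):
    seed: int = 0
    output_dir: str = "lysoflow_output"
    nanoparticle: NanoparticleSection = NanoparticleSection()
    field: FieldSection = FieldSection()
    lysosome: LysosomeSection = LysosomeSection()
    assembly: AssemblySection = AssemblySection()
    thresholds: ThresholdSection | None = None
    solver: SolverSection = SolverSection()
    synthetic: SyntheticSection = SyntheticSection()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise InvalidParameterError(f"invalid configuration {path}:\n{exc}") from exc


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace('"', '\\"') + '"'
    if isinstance(v, Sequence):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {type(v)} to TOML")


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration as TOML (one section per
    sub-model), so every run records the parameters it actually used."""
    data = cfg.model_dump()
    lines = []
    for key, val in data.items():
        if not isinstance(val, dict):
            if val is not None:
                lines.append(f"{key} = {_toml_value(val)}")
    for key, val in data.items():
        if isinstance(val, dict):
            lines.append("")
            lines.append(f"[{key}]")
            for k, v in val.items():
                if v is not None:
                    lines.append(f"{k} = {_toml_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")
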