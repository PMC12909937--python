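"""Lysosome geometry: the spherical arena the nanomotor rotates in."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError

#: Radius (m) of the lysosome used for the reference flow simulations.
REFERENCE_RADIUS = 359.2e-9
#: Dynamic viscosity (Pa s) of lysosomal fluid after nanomotor loading
#: (471.1 cP measured on extracted lysosomal content).
REFERENCE_VISCOSITY = 0.4711
#: Viscosity (Pa s) of lysosomal fluid in untreated cells (90.1 cP).
UNTREATED_VISCOSITY = 0.0901

#: Mean lysosome radius (m) in untreated macrophages / after nanomotor uptake.
MEAN_RADIUS_UNTREATED = 379e-9
MEAN_RADIUS_LOADED = 439e-9


@dataclass(frozen=True)
class LysosomeGeometry:
    """Spherical cavity of radius ``radius`` filled with a Newtonian fluid.

    Parameters
    ----------
    radius:
        Inner radius of the lysosome in metres.
    viscosity:
        Dynamic viscosity of the enclosed fluid in Pa s
        (1 cP = 1e-3 Pa s).
    """

    radius: float = REFERENCE_RADIUS
    viscosity: float = REFERENCE_VISCOSITY

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise InvalidParameterError(f"radius must be > 0, got {self.radius}")
        if not (self.viscosity > 0):
            raise InvalidParameterError(
                f"viscosity must be > 0, got {self.viscosity}"
            )

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius
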