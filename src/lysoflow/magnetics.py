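"""Dipole-chain self-assembly of magnetic nanoparticles under a rotating field.

Cubical superparamagnetic nanoparticles taken up into lysosomes assemble
head-to-tail into rod-like chains when a magnetic field is applied.  Under a
rotating magnetic field (RMF) the equilibrium chain length is set by the
most restrictive of three caps:

* a *geometric* cap -- the rod has to rotate freely inside the lysosome
  without touching the membrane;
* a *fragmentation* (Mason-number) cap -- the hydrodynamic tension at the
  chain midpoint grows as ``eta * omega * L**2`` and snaps the chain once it
  exceeds the head-to-tail dipolar attraction, giving a maximum stable
  length proportional to ``omega**-0.5``;
* a *step-out* cap -- the magnetic torque ``m B`` must exceed the viscous
  torque ``2 pi f xi`` for the chain to rotate synchronously with the field.

All quantities are SI unless noted.  Saturation magnetization is given per
unit mass (A m^2/kg; 1 emu/g = 1 A m^2/kg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import GeometryError, InvalidParameterError
from .geometry import LysosomeGeometry

MU_0 = 4.0e-7 * math.pi  # vacuum permeability (T m / A)

#: Default mass density (kg/m^3) of the magnetic core.  The particles are
#: Zn-doped iron oxide; magnetite (5180 kg/m^3) is used as the default.
DEFAULT_MASS_DENSITY = 5180.0

#: End correction in the slender-body drag denominator ln(L/d) - 0.662 for
#: end-over-end rotation of a rod.
END_OVER_END_CORRECTION = 0.662
#: Additive constant in the transverse slender-body drag density
#: c_perp = 4 pi / (ln(L/d) + 0.84).
TRANSVERSE_DRAG_CONSTANT = 0.84
#: Below this aspect ratio the rod drag falls back to a rotating sphere of
#: radius L/2.  The crossover exp(1/3 + 0.662) makes the two formulas agree
#: exactly at the switch; the slender-body expression is singular at
#: ln(L/d) = 0.662 and non-monotone below the crossover, so it is never
#: evaluated there.
SPHERE_FALLBACK_ASPECT = math.exp(1.0 / 3.0 + END_OVER_END_CORRECTION)


@dataclass(frozen=True)
class Nanoparticle:
    """One cubical magnetic nanoparticle (the force generator).

    Parameters
    ----------
    edge_length:
        Cube edge in metres (default 25.0 nm).
    saturation_magnetization:
        Mass magnetization in A m^2/kg (default 69, i.e. 69 emu/g).
    mass_density:
        Core density in kg/m^3 (default magnetite, 5180).
    coating_thickness:
        Organic coating thickness in metres; enters the centre-to-centre
        spacing of chained particles (default 0: touching cubes).
    """

    edge_length: float = 25.0e-9
    saturation_magnetization: float = 69.0
    mass_density: float = DEFAULT_MASS_DENSITY
    coating_thickness: float = 0.0

    def __post_init__(self) -> None:
        for name in ("edge_length", "saturation_magnetization", "mass_density"):
            if not (getattr(self, name) > 0):
                raise InvalidParameterError(
                    f"{name} must be > 0, got {getattr(self, name)}"
                )
        if self.coating_thickness < 0:
            raise InvalidParameterError("coating_thickness must be >= 0")
        if not (1e-9 < self.edge_length < 1e-6):
            raise InvalidParameterError(
                "edge_length must lie in (1 nm, 1 um), got "
                f"{self.edge_length:g} m"
            )

    @property
    def spacing(self) -> float:
        """Centre-to-centre spacing of adjacent particles in a chain."""
        return self.edge_length + 2.0 * self.coating_thickness

    @property
    def volume(self) -> float:
        return self.edge_length**3

    @property
    def mass(self) -> float:
        return self.mass_density * self.volume


@dataclass(frozen=True)
class RotatingField:
    """Rotating magnetic field: constant-magnitude flux density rotating in
    the xy-plane at ``frequency`` Hz."""

    amplitude: float = 0.26
    frequency: float = 1.0
    duration: float | None = None

    def __post_init__(self) -> None:
        if not (self.amplitude > 0):
            raise InvalidParameterError("amplitude must be > 0")
        if self.frequency < 0:
            raise InvalidParameterError("frequency must be >= 0")
        if self.duration is not None and self.duration <= 0:
            raise InvalidParameterError("duration must be > 0 when given")

    @property
    def angular_velocity(self) -> float:
        """2 pi f (rad/s)."""
        return 2.0 * math.pi * self.frequency


@dataclass(frozen=True)
class AssemblyCriteria:
    """Calibration knobs of the chain-assembly model.

    ``bond_strength_scale`` multiplies the ideal head-to-tail point-dipole
    attraction (it absorbs coating, misalignment and thermal weakening and
    is the parameter recovered from chain-count data).
    ``geometric_fill_fraction`` is the maximum rod length expressed as a
    fraction of the lysosome diameter; the default 0.7 keeps the rotating
    rod clear of the membrane, consistent with electron-microscopy
    observations that assemblies do not touch the lysosomal wall.
    """

    bond_strength_scale: float = 1.0
    geometric_fill_fraction: float = 0.7
    slender_body_end_correction: float = END_OVER_END_CORRECTION

    def __post_init__(self) -> None:
        if not (self.bond_strength_scale > 0):
            raise InvalidParameterError("bond_strength_scale must be > 0")
        if not (0.0 < self.geometric_fill_fraction <= 1.0):
            raise InvalidParameterError(
                "geometric_fill_fraction must lie in (0, 1]"
            )


@dataclass(frozen=True)
class ChainAssembly:
    """An N-particle rod: the rotor driving the intralysosomal flow.

    ``rotational_drag_coeff`` (N m s) is the torque per unit angular
    velocity for end-over-end rotation in the fluid the chain was
    equilibrated in; it is stored because the assembly caps already needed
    it.
    """

    n_particles: int
    spacing: float
    diameter: float
    total_moment: float
    rotational_drag_coeff: float

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise InvalidParameterError("n_particles must be >= 1")
        for name in ("spacing", "diameter", "total_moment"):
            if not (getattr(self, name) > 0):
                raise InvalidParameterError(f"{name} must be > 0")

    @property
    def length(self) -> float:
        """Rod length, exactly ``n_particles * spacing``."""
        return self.n_particles * self.spacing

    @property
    def aspect_ratio(self) -> float:
        return self.length / self.diameter

    @classmethod
    def assemble(
        cls, particle: Nanoparticle, n_particles: int, viscosity: float
    ) -> "ChainAssembly":
        """Build an ``n_particles`` chain of ``particle`` in a fluid of the
        given viscosity (Pa s)."""
        if n_particles < 1:
            raise InvalidParameterError("n_particles must be >= 1")
        m = particle_moment(particle)
        chain = cls(
            n_particles=int(n_particles),
            spacing=particle.spacing,
            diameter=particle.edge_length,
            total_moment=n_particles * m,
            rotational_drag_coeff=1.0,  # placeholder, replaced below
        )
        xi = rotational_drag(chain, viscosity)
        object.__setattr__(chain, "rotational_drag_coeff", xi)
        return chain


def particle_moment(particle: Nanoparticle) -> float:
    """Magnetic moment (A m^2) of a single saturated particle.

    ``m = M_s * rho * a^3`` for a cube of edge ``a``.

    >>> round(particle_moment(Nanoparticle()) / 1e-18, 3)
    5.585
    """
    return (
        particle.saturation_magnetization
        * particle.mass_density
        * particle.edge_length**3
    )


def dipole_bond_force(particle: Nanoparticle, spacing: float | None = None) -> float:
    """Attractive force (N) between two head-to-tail point dipoles.

    ``F = 3 mu_0 m^2 / (2 pi s^4)`` with ``s`` the centre-to-centre
    spacing.  For the default particle this is ~48 pN, the piconewton force
    scale expected for magnetically actuated nanoparticles.
    """
    if spacing is None:
        spacing = particle.spacing
    if spacing < particle.edge_length:
        raise GeometryError(
            f"spacing {spacing:g} m is below the particle edge "
            f"{particle.edge_length:g} m: cubes would interpenetrate"
        )
    m = particle_moment(particle)
    return 3.0 * MU_0 * m**2 / (2.0 * math.pi * spacing**4)


def rotational_drag(chain: ChainAssembly, viscosity: float) -> float:
    """Rotational drag coefficient (N m s) for end-over-end rotation.

    Slender-body result ``xi = pi eta L^3 / (3 (ln(L/d) - 0.662))``; for
    compact aspect ratios (below ~2.7, where the slender-body expression
    degenerates) the rotating-sphere coefficient ``8 pi eta a^3`` with
    ``a = L/2`` is used instead; the two agree at the crossover.
    """
    if not (viscosity > 0):
        raise InvalidParameterError("viscosity must be > 0")
    L, d = chain.length, chain.diameter
    if chain.aspect_ratio <= SPHERE_FALLBACK_ASPECT:
        return 8.0 * math.pi * viscosity * (L / 2.0) ** 3
    return (
        math.pi
        * viscosity
        * L**3
        / (3.0 * (math.log(L / d) - END_OVER_END_CORRECTION))
    )


def step_out_frequency(
    chain: ChainAssembly, field: RotatingField, viscosity: float
) -> float:
    """Largest field frequency (Hz) the chain can follow synchronously.

    Balancing the maximum magnetic torque ``m B`` against the viscous
    torque ``xi omega`` gives ``f_so = m B / (2 pi xi)``.  For
    ``f <= f_so`` the chain rotates at the field frequency with a constant
    phase lag ``arcsin(f / f_so)``.
    """
    xi = rotational_drag(chain, viscosity)
    return chain.total_moment * field.amplitude / (2.0 * math.pi * xi)


def synchronous_phase_lag(
    chain: ChainAssembly, field: RotatingField, viscosity: float
) -> float:
    """Phase lag (rad) between the field and the chain axis in the
    synchronous regime; ``pi/2`` exactly at step-out."""
    f_so = step_out_frequency(chain, field, viscosity)
    ratio = field.frequency / f_so
    if ratio > 1.0:
        raise InvalidParameterError(
            f"frequency {field.frequency:g} Hz exceeds the step-out "
            f"frequency {f_so:g} Hz: no synchronous rotation"
        )
    return math.asin(ratio)


def transverse_drag_density(length: float, diameter: float) -> float:
    """Transverse slender-body drag density ``c_perp = 4 pi / (ln(L/d) + 0.84)``
    (dimensionless multiplier of ``eta``)."""
    if length <= diameter:
        raise GeometryError("transverse drag density requires L > d")
    return 4.0 * math.pi / (math.log(length / diameter) + TRANSVERSE_DRAG_CONSTANT)


def fragmentation_length(
    particle: Nanoparticle,
    criteria: AssemblyCriteria,
    field: RotatingField,
    viscosity: float,
    *,
    max_iter: int = 200,
    rtol: float = 1e-12,
) -> float:
    """Maximum chain length (m) stable against centrifugal fragmentation.

    The hydrodynamic tension at the midpoint of a rotating rod is
    ``c_perp eta omega L^2 / 8``; equating it to the (scaled) dipolar bond
    force gives ``L_max = sqrt(8 k F_bond / (c_perp eta omega))``.  Because
    ``c_perp`` itself depends weakly (logarithmically) on ``L``, the
    equation is solved by fixed-point iteration.

    Returns ``inf`` for a static field (frequency 0): without rotation the
    chain never fragments.
    """
    if not (viscosity > 0):
        raise InvalidParameterError("viscosity must be > 0")
    if field.frequency == 0.0:
        return math.inf
    omega = field.angular_velocity
    f_bond = criteria.bond_strength_scale * dipole_bond_force(particle)
    d = particle.edge_length
    L = 10.0 * d  # starting guess; converges in a handful of iterations
    for _ in range(max_iter):
        c_perp = transverse_drag_density(max(L, 1.5 * d), d)
        L_new = math.sqrt(8.0 * f_bond / (c_perp * viscosity * omega))
        if abs(L_new - L) <= rtol * L:
            return L_new
        L = L_new
    return L


def equilibrium_chain(
    particle: Nanoparticle,
    criteria: AssemblyCriteria,
    field: RotatingField,
    lysosome: LysosomeGeometry,
    viscosity: float | None = None,
) -> ChainAssembly:
    """Equilibrium chain under the three assembly caps.

    ``n = floor(min(geometric cap, fragmentation cap, step-out cap) / s)``,
    clipped below at one particle.  Only the geometric cap can make
    assembly impossible outright (a lysosome smaller than one particle).
    """
    if viscosity is None:
        viscosity = lysosome.viscosity
    s = particle.spacing
    geo_cap = criteria.geometric_fill_fraction * lysosome.diameter
    n_geo = math.floor(geo_cap / s)
    if n_geo < 1:
        raise GeometryError(
            f"geometric cap {geo_cap:g} m admits no particle of spacing {s:g} m"
        )
    n = n_geo
    if field.frequency > 0:
        L_frag = fragmentation_length(particle, criteria, field, viscosity)
        if math.isfinite(L_frag):
            n = min(n, max(1, math.floor(L_frag / s)))
        # step-out cap: longest chain still able to follow the field
        while n > 1:
            chain = ChainAssembly.assemble(particle, n, viscosity)
            if step_out_frequency(chain, field, viscosity) >= field.frequency:
                break
            n -= 1
    return ChainAssembly.assemble(particle, n, viscosity)
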