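"""Stokes flow of lysosomal fluid driven by a rotating nanomotor rod.

The rotor (a capsule approximating the assembled nanoparticle chain) spins
about the z-axis inside a rigid sphere filled with Newtonian fluid.  At
organelle scale the Reynolds number is ~1e-7, so a quasi-static snapshot of
the incompressible steady Stokes equations with rigid-body velocity on the
rod surface and no slip on the lysosomal wall describes the flow; all
fields are exactly linear in the angular velocity and the viscosity, and a
single unit solve per geometry is rescaled to any (omega, eta).

The discretisation is a Stokeslet-collocation scheme (see
``lysoflow._stokeslets``).  Its accuracy is controlled by one scalar
``resolution`` knob; the default (1.0) matches the concentric-spheres
closed form to well under one percent in wall shear and torque.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _stokeslets as mfs
from .errors import GeometryError, InvalidParameterError, SolverError, StateError
from .geometry import LysosomeGeometry
from .magnetics import (
    AssemblyCriteria,
    ChainAssembly,
    Nanoparticle,
    RotatingField,
    equilibrium_chain,
)

__all__ = [
    "LysosomeGeometry",
    "FlowSolution",
    "ShearSpectrum",
    "CenteringForce",
    "ConcentricSpheresFlow",
    "solve_rotating_rod",
    "solve_rotating_sphere",
    "sphere_in_sphere_oracle",
    "wall_shear_profile",
    "centering_force",
    "shear_spectrum",
    "clear_solver_cache",
]

#: Default mass density of lysosomal fluid (kg/m^3), used only by the
#: inertial force correction; the Stokes fields are density-free.
FLUID_DENSITY = 1100.0

#: Default tolerances for the solution diagnostics (relative).
DIVERGENCE_TOL = 1e-8
BC_TOL_WALL = 5e-3
BC_TOL_ROD = 0.35  # localised max near the capsule tip junction; see docs
TORQUE_BALANCE_TOL = 0.01

_SPECTRUM_COLUMNS = [
    "frequency_hz",
    "n_particles",
    "chain_length_m",
    "max_velocity_m_s",
    "max_wall_shear_pa",
]


# --------------------------------------------------------------------------
# closed-form oracle: solid sphere rotating inside a concentric fixed sphere
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcentricSpheresFlow:
    """Classical Stokes solution for a solid sphere of radius ``b``
    rotating at ``omega`` about z inside a fixed concentric sphere of
    radius ``R``: ``u_phi(r, theta) = (A r + B / r^2) sin(theta)``."""

    inner_radius: float
    outer_radius: float
    viscosity: float
    angular_velocity: float

    def __post_init__(self):
        if not (0.0 < self.inner_radius < self.outer_radius):
            raise GeometryError(
                "need 0 < inner radius < outer radius, got "
                f"{self.inner_radius:g} and {self.outer_radius:g}"
            )

    @property
    def _coeffs(self) -> tuple[float, float]:
        b3 = self.inner_radius**3
        r3 = self.outer_radius**3
        denom = r3 - b3
        a = -self.angular_velocity * b3 / denom
        bb = self.angular_velocity * b3 * r3 / denom
        return a, bb

    def azimuthal_velocity(self, r, theta=np.pi / 2.0):
        """u_phi at radius r (m) and polar angle theta."""
        a, bb = self._coeffs
        r = np.asarray(r, dtype=float)
        return (a * r + bb / r**2) * np.sin(theta)

    def wall_shear(self, theta):
        """|sigma_{r phi}| on the outer sphere: ``3 eta Omega b^3 /
        (R^3 - b^3) * sin(theta)``."""
        return self.equatorial_wall_shear * np.abs(np.sin(np.asarray(theta)))

    @property
    def equatorial_wall_shear(self) -> float:
        b3 = self.inner_radius**3
        r3 = self.outer_radius**3
        return 3.0 * self.viscosity * abs(self.angular_velocity) * b3 / (r3 - b3)

    @property
    def rotor_torque_magnitude(self) -> float:
        """|T| = 8 pi eta Omega b^3 R^3 / (R^3 - b^3) (interior-corrected
        rotating-sphere torque)."""
        b3 = self.inner_radius**3
        r3 = self.outer_radius**3
        return 8.0 * math.pi * self.viscosity * abs(self.angular_velocity) * b3 * r3 / (r3 - b3)


def sphere_in_sphere_oracle(
    inner_radius: float, lysosome: LysosomeGeometry, angular_velocity: float
) -> float:
    """Equatorial wall shear stress (Pa) of the concentric rotating-spheres
    closed form; the validation oracle for the numerical solver."""
    flow = ConcentricSpheresFlow(
        inner_radius, lysosome.radius, lysosome.viscosity, angular_velocity
    )
    return flow.equatorial_wall_shear


# --------------------------------------------------------------------------
# numerical solution container
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FlowSolution:
    """Discretised Stokes solution for one rotor geometry and actuation.

    Fields are sampled on an unstructured point cloud: interior points
    (``mesh_points``) carry velocity and pressure; wall samples carry the
    traction split into shear (tangential) magnitude.  Torques are 3-vectors
    about the lysosome centre.  ``divergence_residual`` and the boundary
    residuals are dimensionless (normalised by the rotor tip speed and the
    lysosome radius).
    """

    mesh_points: np.ndarray
    velocity_field: np.ndarray
    pressure_field: np.ndarray
    wall_points: np.ndarray
    wall_normals: np.ndarray
    wall_weights: np.ndarray
    wall_shear: np.ndarray
    wall_traction: np.ndarray
    max_velocity: float
    max_wall_shear: float
    rod_force: np.ndarray
    rod_torque: np.ndarray
    wall_torque: np.ndarray
    divergence_residual: float
    bc_residual: float
    bc_residual_wall: float
    angular_velocity: float
    viscosity: float
    lysosome_radius: float
    rotor_length: float
    rotor_diameter: float
    offset: np.ndarray
    _unit: mfs.UnitStokesSolution | None = None

    @property
    def torque_balance(self) -> float:
        """|T_rod + T_wall| / |T_rod|; zero for an exact solution."""
        denom = np.linalg.norm(self.rod_torque)
        if denom == 0.0:
            return 0.0
        return float(np.linalg.norm(self.rod_torque + self.wall_torque) / denom)

    def rescaled(self, angular_velocity: float, viscosity: float | None = None) -> "FlowSolution":
        """Exact linear rescaling to a new angular velocity / viscosity.

        Velocities scale with omega, stresses and torques with eta * omega;
        residual diagnostics are scale-free and carry over unchanged.
        """
        eta = self.viscosity if viscosity is None else viscosity
        ku = angular_velocity / self.angular_velocity
        ks = (eta * angular_velocity) / (self.viscosity * self.angular_velocity)
        return replace(
            self,
            velocity_field=self.velocity_field * ku,
            pressure_field=self.pressure_field * ks,
            wall_shear=self.wall_shear * ks,
            wall_traction=self.wall_traction * ks,
            max_velocity=self.max_velocity * ku,
            max_wall_shear=self.max_wall_shear * ks,
            rod_force=self.rod_force * ks,
            rod_torque=self.rod_torque * ks,
            wall_torque=self.wall_torque * ks,
            angular_velocity=angular_velocity,
            viscosity=eta,
        )


# --------------------------------------------------------------------------
# geometry discretisation and unit-solve cache
# --------------------------------------------------------------------------

_WALL_SOURCE_INFLATION = 1.55
_ROD_SOURCE_RADIUS_FRACTION = 0.45
_ROD_SOURCE_TIP_STANDOFF = 1.0  # in rod radii
_SPHERE_SOURCE_RADIUS_FRACTION = 0.55

_unit_cache: dict[tuple, mfs.UnitStokesSolution] = {}
_MAX_CACHE = 8


def clear_solver_cache() -> None:
    _unit_cache.clear()


def _wall_clouds(radius: float, resolution: float) -> tuple[mfs.SurfaceCloud, np.ndarray]:
    n_t = max(int(round(26 * resolution)), 8)
    coll = mfs.sphere_cloud(radius, n_t, 2 * n_t)
    n_ts = max(int(round(n_t * 0.65)), 6)
    src = mfs.sphere_cloud(_WALL_SOURCE_INFLATION * radius, n_ts, 2 * n_ts)
    return coll, src.points


def _rod_clouds(
    length: float, radius: float, resolution: float
) -> tuple[mfs.SurfaceCloud, np.ndarray]:
    h_coll = 0.55 * radius / resolution
    coll = mfs.capsule_cloud(length, radius, h_coll)
    a_src = _ROD_SOURCE_RADIUS_FRACTION * radius
    len_src = length - 2.0 * _ROD_SOURCE_TIP_STANDOFF * radius
    len_src = max(len_src, 2.5 * a_src)
    src = mfs.capsule_cloud(len_src, a_src, 0.5 * radius / resolution)
    return coll, src.points


def _sphere_rotor_clouds(
    radius: float, resolution: float
) -> tuple[mfs.SurfaceCloud, np.ndarray]:
    n_t = max(int(round(14 * resolution)), 6)
    coll = mfs.sphere_cloud(radius, n_t, 2 * n_t)
    n_ts = max(int(round(n_t * 0.6)), 4)
    src = mfs.sphere_cloud(_SPHERE_SOURCE_RADIUS_FRACTION * radius, n_ts, 2 * n_ts)
    return coll, src.points


def _unit_solution(
    kind: str,
    lysosome_radius: float,
    rotor_length: float,
    rotor_radius: float,
    offset: np.ndarray,
    resolution: float,
) -> mfs.UnitStokesSolution:
    key = (
        kind,
        round(lysosome_radius, 15),
        round(rotor_length, 15),
        round(rotor_radius, 15),
        tuple(np.round(offset, 15)),
        round(resolution, 6),
    )
    if key in _unit_cache:
        return _unit_cache[key]
    wall_coll, wall_src = _wall_clouds(lysosome_radius, resolution)
    if kind == "rod":
        rot_coll, rot_src = _rod_clouds(rotor_length, rotor_radius, resolution)
    else:
        rot_coll, rot_src = _sphere_rotor_clouds(rotor_radius, resolution)
    rot_coll = rot_coll.translated(offset)
    rot_src = rot_src + offset
    unit = mfs.solve_unit_problem(rot_coll, rot_src, wall_coll, wall_src)
    unit.meta.update(
        kind=kind,
        lysosome_radius=lysosome_radius,
        rotor_length=rotor_length,
        rotor_radius=rotor_radius,
        offset=np.asarray(offset, dtype=float),
        resolution=resolution,
    )
    if len(_unit_cache) >= _MAX_CACHE:
        _unit_cache.pop(next(iter(_unit_cache)))
    _unit_cache[key] = unit
    return unit


def _interior_mesh(
    lysosome_radius: float, offset: np.ndarray, half_len: float, rotor_radius: float
) -> np.ndarray:
    """Point cloud for field output: spherical shells, rotor interior
    excluded."""
    shells = np.linspace(0.15, 0.97, 9) * lysosome_radius
    mu = np.linspace(-0.95, 0.95, 11)
    phi = np.arange(20) * (2.0 * np.pi / 20)
    rr, mm, pp = np.meshgrid(shells, mu, phi, indexing="ij")
    st = np.sqrt(1.0 - mm**2)
    pts = np.stack(
        [rr * st * np.cos(pp), rr * st * np.sin(pp), rr * mm], axis=-1
    ).reshape(-1, 3)
    keep = _capsule_distance(pts, offset, half_len) > 1.05 * rotor_radius
    return pts[keep]


def _capsule_distance(points: np.ndarray, offset: np.ndarray, half_len: float) -> np.ndarray:
    """Distance from points to the capsule axis segment (centre ``offset``,
    along x, half-length ``half_len`` of the cylindrical part)."""
    q = points - offset
    x = np.clip(q[:, 0], -half_len, half_len)
    q = q.copy()
    q[:, 0] -= x
    return np.linalg.norm(q, axis=1)


def _build_solution(
    unit: mfs.UnitStokesSolution,
    angular_velocity: float,
    viscosity: float,
) -> FlowSolution:
    meta = unit.meta
    radius = meta["lysosome_radius"]
    offset = meta["offset"]
    rotor_len = meta["rotor_length"]
    rotor_rad = meta["rotor_radius"]
    half_len = max(rotor_len / 2.0 - rotor_rad, 0.0)

    mesh = _interior_mesh(radius, offset, half_len, rotor_rad)
    u_unit, gu = mfs.evaluate_velocity_and_gradient(mesh, unit.sources, unit.strengths)
    p_unit = mfs.evaluate_pressure(mesh, unit.sources, unit.strengths)

    wall = unit.wall_surface
    # traction exerted by the fluid on the membrane: Cauchy stress acting on
    # the wall's outward normal, which points *into* the fluid (-r hat)
    tract_unit = -mfs.wall_traction(
        wall.points, wall.normals, unit.sources, unit.strengths
    )
    normal_comp = np.einsum("mi,mi->m", tract_unit, wall.normals)
    shear_vec_unit = tract_unit - normal_comp[:, None] * wall.normals
    shear_unit = np.linalg.norm(shear_vec_unit, axis=1)

    # torque on rotor = -sum(y x f) over rotor sources (sources sit inside
    # the rotor, so the traction integral reduces to the source strengths)
    n_rot = unit.n_rotor_sources
    f_rod_unit = -unit.strengths[:n_rot].sum(axis=0)
    t_rod_unit = -np.cross(unit.sources[:n_rot], unit.strengths[:n_rot]).sum(axis=0)
    # torque on wall from the traction quadrature (independent estimate)
    t_wall_unit = np.einsum(
        "m,mi->i", wall.weights, np.cross(wall.points, tract_unit)
    )

    # rigid-body speed on the rotor surface dominates the fluid speed
    rotor_speed = np.linalg.norm(
        np.cross([0.0, 0.0, 1.0], unit.rotor_surface.points), axis=1
    ).max()
    max_u_unit = max(float(np.linalg.norm(u_unit, axis=1).max()), float(rotor_speed))

    div_unit = np.abs(np.einsum("mii->m", gu)).max()
    u_scale = rotor_speed
    divergence_residual = float(div_unit * radius / u_scale)

    ku = angular_velocity
    ks = viscosity * angular_velocity
    return FlowSolution(
        mesh_points=mesh,
        velocity_field=u_unit * ku,
        pressure_field=p_unit * ks,
        wall_points=wall.points,
        wall_normals=wall.normals,
        wall_weights=wall.weights,
        wall_shear=shear_unit * ks,
        wall_traction=tract_unit * ks,
        max_velocity=max_u_unit * ku,
        max_wall_shear=float(shear_unit.max()) * ks,
        rod_force=f_rod_unit * ks,
        rod_torque=t_rod_unit * ks,
        wall_torque=t_wall_unit * ks,
        divergence_residual=divergence_residual,
        bc_residual=unit.bc_residual_rod,
        bc_residual_wall=unit.bc_residual_wall,
        angular_velocity=angular_velocity,
        viscosity=viscosity,
        lysosome_radius=radius,
        rotor_length=rotor_len,
        rotor_diameter=2.0 * rotor_rad,
        offset=offset,
        _unit=unit,
    )


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------


def solve_rotating_rod(
    lysosome: LysosomeGeometry,
    chain: ChainAssembly,
    angular_velocity: float,
    offset: np.ndarray | tuple = (0.0, 0.0, 0.0),
    resolution: float = 1.0,
) -> FlowSolution:
    """Quasi-static Stokes solve for the chain rotating about z inside the
    lysosome.

    The rod is modelled as a capsule of diameter equal to the particle edge
    (the cube-chain corrugation is below solver resolution), instantaneously
    along x, rotating rigidly about the lysosome's z-axis.  The rod must fit:
    ``|offset| + L/2 + d/2 < R``.
    """
    offset = np.asarray(offset, dtype=float)
    if offset.shape != (3,):
        raise InvalidParameterError("offset must be a 3-vector")
    reach = np.linalg.norm(offset) + chain.length / 2.0 + chain.diameter / 2.0
    if reach >= lysosome.radius:
        raise GeometryError(
            f"rod does not fit: offset + L/2 + d/2 = {reach:g} m >= "
            f"lysosome radius {lysosome.radius:g} m"
        )
    if resolution <= 0:
        raise InvalidParameterError("resolution must be > 0")
    unit = _unit_solution(
        "rod",
        lysosome.radius,
        chain.length,
        chain.diameter / 2.0,
        offset,
        resolution,
    )
    sol = _build_solution(unit, float(angular_velocity), lysosome.viscosity)
    _check_solution(sol)
    return sol


def solve_rotating_sphere(
    inner_radius: float,
    lysosome: LysosomeGeometry,
    angular_velocity: float,
    resolution: float = 1.0,
) -> FlowSolution:
    """Numerical solve with a solid spherical rotor (validation geometry
    matching :func:`sphere_in_sphere_oracle`)."""
    if not (0.0 < inner_radius < lysosome.radius):
        raise GeometryError("need 0 < rotor radius < lysosome radius")
    unit = _unit_solution(
        "sphere",
        lysosome.radius,
        2.0 * inner_radius,
        inner_radius,
        np.zeros(3),
        resolution,
    )
    sol = _build_solution(unit, float(angular_velocity), lysosome.viscosity)
    _check_solution(sol)
    return sol


def _check_solution(sol: FlowSolution) -> None:
    if sol.divergence_residual > DIVERGENCE_TOL:
        raise SolverError(
            "divergence residual above tolerance",
            {"divergence_residual": sol.divergence_residual},
        )
    if sol.bc_residual_wall > BC_TOL_WALL or sol.bc_residual > BC_TOL_ROD:
        raise SolverError(
            "boundary-condition residual above tolerance",
            {
                "bc_residual_rod": sol.bc_residual,
                "bc_residual_wall": sol.bc_residual_wall,
            },
        )


def wall_shear_profile(sol: FlowSolution) -> pd.DataFrame:
    """Wall shear-stress distribution of a solved flow.

    Returns a DataFrame with the wall sample coordinates, polar angle
    ``theta`` (from the rotation axis z), azimuth ``phi`` and the shear
    magnitude; its maximum equals ``sol.max_wall_shear``.
    """
    if sol.wall_shear is None or len(sol.wall_shear) == 0:
        raise StateError("flow solution carries no wall samples")
    x, y, z = sol.wall_points.T
    r = np.linalg.norm(sol.wall_points, axis=1)
    return pd.DataFrame(
        {
            "x_m": x,
            "y_m": y,
            "z_m": z,
            "theta_rad": np.arccos(np.clip(z / r, -1.0, 1.0)),
            "phi_rad": np.arctan2(y, x),
            "shear_pa": sol.wall_shear,
        }
    )


@dataclass(frozen=True)
class CenteringForce:
    """Cycle-averaged hydraulic force on a tumbling rod, split by origin.

    ``stokes`` is the rotation-cycle average of the quasi-static Stokes
    traction integral.  Kinematic reversibility makes it vanish exactly
    (each instantaneous lateral force is cancelled by the mirrored rotation
    phase), so the returned vector is a pure discretisation residue and is
    reported only as a diagnostic.  ``inertial`` is the first-order
    fluid-inertia correction, computed per phase with the Lorentz
    reciprocal theorem and averaged over the cycle; it is the leading
    non-vanishing lateral force and the term that centres (or de-centres)
    the rotor.  ``along_offset`` projects the inertial force onto the
    offset direction: negative means restoring, i.e. the pressure build-up
    on the membrane-proximal side pushes the rod back towards the centre.
    """

    stokes: np.ndarray
    inertial: np.ndarray
    offset: np.ndarray
    n_phases: int

    @property
    def total(self) -> np.ndarray:
        return self.stokes + self.inertial

    @property
    def along_offset(self) -> float:
        norm = np.linalg.norm(self.offset)
        if norm == 0.0:
            return 0.0
        return float(self.inertial @ (self.offset / norm))


def _volume_quadrature(radius: float, grid: tuple[int, int, int]):
    """Gauss-Legendre (r, cos theta) x uniform azimuth quadrature over the
    ball; mirror-symmetric so symmetry-forbidden force components cancel."""
    n_r, n_t, n_p = grid
    xr, w_r = np.polynomial.legendre.leggauss(n_r)
    r = (xr + 1.0) / 2.0 * radius
    w_r = w_r * radius / 2.0
    mu, w_mu = np.polynomial.legendre.leggauss(n_t)
    phi = np.arange(n_p) * (2.0 * np.pi / n_p)
    rr, mm, pp = np.meshgrid(r, mu, phi, indexing="ij")
    st = np.sqrt(1.0 - mm**2)
    pts = np.stack(
        [rr * st * np.cos(pp), rr * st * np.sin(pp), rr * mm], -1
    ).reshape(-1, 3)
    wts = (
        w_r[:, None, None] * w_mu[None, :, None] * (2.0 * np.pi / n_p) * rr**2
    ).ravel()
    return pts, wts


def _rot_z(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def centering_force(
    lysosome: LysosomeGeometry,
    chain: ChainAssembly,
    angular_velocity: float,
    offset: np.ndarray | tuple = (0.0, 0.0, 0.0),
    resolution: float = 1.0,
    fluid_density: float = FLUID_DENSITY,
    n_phases: int = 4,
    volume_grid: tuple[int, int, int] = (32, 28, 48),
) -> CenteringForce:
    """Cycle-averaged hydraulic force on a rod tumbling about its own
    centre at the given offset from the lysosome centre.

    The rod spins about the z-axis through its own centre (the magnetic
    torque prescribes rotation, not translation, so a displaced rod tumbles
    where it sits).  The instantaneous flow is quasi-static Stokes, solved
    at ``n_phases`` rod orientations over half a turn (the rod is
    fore-aft symmetric, so the force is pi-periodic).  Per phase the
    first-order inertial force is obtained from the reciprocal theorem

        F . e = -rho * int (du/dt + (u . grad) u) . u_hat dV,

    with ``u_hat`` the auxiliary Stokes field for unit rod translation
    along ``e`` and the unsteady term computed exactly from a
    shape-derivative right-hand side on the same collocation matrix.
    """
    offset = np.asarray(offset, dtype=float)
    if offset.shape != (3,):
        raise InvalidParameterError("offset must be a 3-vector")
    reach = np.linalg.norm(offset) + chain.length / 2.0 + chain.diameter / 2.0
    if reach >= lysosome.radius:
        raise GeometryError(
            f"rod does not fit at offset: reach {reach:g} m >= radius "
            f"{lysosome.radius:g} m"
        )
    omega = float(angular_velocity)
    eta = lysosome.viscosity
    a_rod = chain.diameter / 2.0
    half_len = max(chain.length / 2.0 - a_rod, 0.0)
    norm_off = np.linalg.norm(offset)
    e_off = offset / norm_off if norm_off > 0 else np.array([1.0, 0.0, 0.0])

    pts_all, wts_all = _volume_quadrature(lysosome.radius, volume_grid)
    wall_coll, wall_src = _wall_clouds(lysosome.radius, resolution)
    rod_coll0, rod_src0 = _rod_clouds(chain.length, a_rod, resolution)

    z_hat = np.array([0.0, 0.0, 1.0])
    f_stokes = np.zeros(3)
    f_inertial = np.zeros(3)
    for k in range(n_phases):
        theta = k * math.pi / n_phases
        rot = _rot_z(theta)
        rod_coll = mfs.SurfaceCloud(
            rod_coll0.points @ rot.T + offset,
            rod_coll0.weights,
            rod_coll0.normals @ rot.T,
        )
        rod_src = rod_src0 @ rot.T + offset
        system = mfs.CollocationSystem(rod_coll, rod_src, wall_coll, wall_src)

        x_rod = rod_coll.points
        u_bc = omega * np.cross(z_hat, x_rod - offset)
        f0 = system.solve_rotor_bc(u_bc)
        f_aux = system.solve_rotor_bc(np.broadcast_to(e_off, x_rod.shape))
        # shape-derivative BC for w = du/dtheta on the tumbling rod:
        # w = Omega_hat x u_bc/omega ... assembled from the rigid identity
        _, grad_on_rod = mfs.evaluate_velocity_and_gradient(
            x_rod, system.sources, f0
        )
        zxr = np.cross(z_hat, x_rod - offset)
        w_bc = omega * np.cross(z_hat, zxr) - np.einsum(
            "mk,mik->mi", zxr, grad_on_rod
        )
        f_w = system.solve_rotor_bc(w_bc)

        n_src_rod = system.n_rotor_sources
        f_stokes += -f0[:n_src_rod].sum(axis=0) * eta

        q = (pts_all - offset) @ rot
        xx = np.clip(q[:, 0], -half_len, half_len)
        q = q.copy()
        q[:, 0] -= xx
        keep = np.linalg.norm(q, axis=1) > 1.001 * a_rod
        pts, wts = pts_all[keep], wts_all[keep]
        u, gu = mfs.evaluate_velocity_and_gradient(pts, system.sources, f0)
        u_w, _ = mfs.evaluate_velocity_and_gradient(
            pts, system.sources, f_w, with_gradient=False
        )
        u_hat, _ = mfs.evaluate_velocity_and_gradient(
            pts, system.sources, f_aux, with_gradient=False
        )
        accel = omega * u_w + np.einsum("mk,mik->mi", u, gu)
        f_x = -fluid_density * (wts * np.einsum("mi,mi->m", accel, u_hat)).sum()
        f_inertial += f_x * e_off

    return CenteringForce(
        stokes=f_stokes / n_phases,
        inertial=f_inertial / n_phases,
        offset=offset,
        n_phases=n_phases,
    )


@dataclass(frozen=True)
class ShearSpectrum:
    """Frequency-indexed table coupling assembly state to flow maxima
    (columns: frequency_hz, n_particles, chain_length_m, max_velocity_m_s,
    max_wall_shear_pa)."""

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if list(t.columns) != _SPECTRUM_COLUMNS:
            raise InvalidParameterError(f"spectrum columns must be {_SPECTRUM_COLUMNS}")
        f = t["frequency_hz"].to_numpy()
        if np.any(np.diff(f) <= 0):
            raise InvalidParameterError("frequencies must be strictly increasing")
        if (t[_SPECTRUM_COLUMNS[1:]].to_numpy() < 0).any():
            raise InvalidParameterError("spectrum magnitudes must be >= 0")

    def max_wall_shear_at(self, frequency: float) -> float:
        t = self.table
        row = t[np.isclose(t["frequency_hz"], frequency)]
        if row.empty:
            raise InvalidParameterError(f"frequency {frequency} Hz not in spectrum")
        return float(row["max_wall_shear_pa"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def shear_spectrum(
    frequencies,
    particle: Nanoparticle,
    criteria: AssemblyCriteria,
    field: RotatingField,
    lysosome: LysosomeGeometry,
    resolution: float = 1.0,
    chain: ChainAssembly | None = None,
) -> ShearSpectrum:
    """Sweep RMF frequencies: re-equilibrate the chain at each frequency,
    solve the centred-rod flow and record the hydrodynamic maxima.

    Passing an explicit ``chain`` disables re-assembly (fixed rotor), in
    which case every column is exactly linear in frequency.  Solutions are
    cached per geometry and rescaled, so a sweep over frequencies with an
    unchanged chain costs a single solve.
    """
    freqs = [float(f) for f in frequencies]
    if any(f <= 0 for f in freqs):
        raise InvalidParameterError("frequencies must be > 0")
    if any(b <= a for a, b in zip(freqs, freqs[1:])):
        raise InvalidParameterError("frequencies must be strictly increasing")
    rows = []
    for f in freqs:
        field_f = RotatingField(field.amplitude, f, field.duration)
        ch = chain if chain is not None else equilibrium_chain(
            particle, criteria, field_f, lysosome
        )
        sol = solve_rotating_rod(lysosome, ch, 2.0 * math.pi * f, resolution=resolution)
        rows.append(
            {
                "frequency_hz": f,
                "n_particles": ch.n_particles,
                "chain_length_m": ch.length,
                "max_velocity_m_s": sol.max_velocity,
                "max_wall_shear_pa": sol.max_wall_shear,
            }
        )
    return ShearSpectrum(pd.DataFrame(rows, columns=_SPECTRUM_COLUMNS))
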