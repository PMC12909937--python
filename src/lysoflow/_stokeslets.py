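"""Stokeslet-collocation (method of fundamental solutions) core.

The steady Stokes problem inside the lysosome is solved by representing the
velocity field as a finite sum of point-force (Stokeslet) fundamental
solutions whose singularities lie *outside* the fluid: on a shrunken
capsule inside the rotor and on an inflated sphere outside the lysosomal
wall.  No-slip boundary conditions are collocated on the physical surfaces
in a weighted least-squares sense.  Because each Stokeslet satisfies the
incompressible Stokes equations exactly, the represented field is
divergence-free to machine precision and velocity, pressure, velocity
gradient and traction can all be evaluated analytically anywhere in the
fluid.

Conventions: lengths in metres, velocities in m/s, stresses in Pa.  The
unit problem is solved with viscosity 1 Pa s and unit angular velocity;
callers rescale by linearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lstsq

__all__ = [
    "SurfaceCloud",
    "sphere_cloud",
    "capsule_cloud",
    "velocity_matrix",
    "evaluate_velocity_and_gradient",
    "evaluate_pressure",
    "wall_traction",
    "solve_unit_problem",
    "UnitStokesSolution",
]

_FOUR_PI = 4.0 * np.pi
_EIGHT_PI = 8.0 * np.pi


@dataclass
class SurfaceCloud:
    """Quasi-uniform point sampling of a closed surface.

    ``points`` (n, 3), ``weights`` (n,) quadrature areas in m^2 and
    ``normals`` (n, 3) outward unit normals.
    """

    points: np.ndarray
    weights: np.ndarray
    normals: np.ndarray

    def translated(self, offset: np.ndarray) -> "SurfaceCloud":
        return SurfaceCloud(self.points + offset, self.weights, self.normals)

    def __len__(self) -> int:
        return len(self.points)


def sphere_cloud(radius: float, n_theta: int, n_phi: int) -> SurfaceCloud:
    """Gauss-Legendre x uniform-azimuth product grid on a sphere.

    The grid is symmetric under the reflections z -> -z and y -> -y, which
    keeps discretely computed forces free of spurious symmetry-breaking
    components.
    """
    mu, w_mu = np.polynomial.legendre.leggauss(n_theta)
    phi = np.arange(n_phi) * (2.0 * np.pi / n_phi)
    st = np.sqrt(1.0 - mu**2)
    x = np.outer(st, np.cos(phi))
    y = np.outer(st, np.sin(phi))
    z = np.outer(mu, np.ones(n_phi))
    normals = np.stack([x, y, z], axis=-1).reshape(-1, 3)
    points = radius * normals
    weights = np.outer(w_mu, np.full(n_phi, 2.0 * np.pi / n_phi)).ravel() * radius**2
    return SurfaceCloud(points, weights, normals)


def capsule_cloud(length: float, radius: float, spacing: float) -> SurfaceCloud:
    """Point sampling of a capsule (cylinder with hemispherical caps).

    The capsule axis is x, total tip-to-tip length ``length`` and cross
    section radius ``radius``.  Ring azimuths are kept unstaggered so the
    cloud is mirror-symmetric in y and z.
    """
    a = radius
    lc = length - 2.0 * a
    if lc < 0:
        raise ValueError("capsule length must be >= 2 * radius")
    n_phi = max(int(np.ceil(2.0 * np.pi * a / spacing)), 6)
    n_phi += n_phi % 2  # even counts keep the y -> -y mirror symmetry
    n_ring = max(int(np.ceil(lc / spacing)), 1)
    xs = np.linspace(-lc / 2.0, lc / 2.0, n_ring + 1)
    phis = np.arange(n_phi) * (2.0 * np.pi / n_phi)
    pts, wts, nrm = [], [], []
    d_area = (lc / n_ring) * (2.0 * np.pi * a / n_phi) if lc > 0 else 0.0
    for i, x in enumerate(xs):
        fac = 0.5 if i in (0, n_ring) else 1.0
        for p in phis:
            c, s = np.cos(p), np.sin(p)
            pts.append([x, a * c, a * s])
            nrm.append([0.0, c, s])
            wts.append(d_area * fac)
    n_lat = max(int(np.ceil((np.pi / 2.0 * a) / spacing)), 3)
    for sign in (1.0, -1.0):
        for j in range(1, n_lat + 1):
            th = (j - 0.5) / n_lat * (np.pi / 2.0)
            rr = a * np.cos(th)
            xx = lc / 2.0 + a * np.sin(th)
            n_pj = max(int(np.ceil(2.0 * np.pi * rr / spacing)), 4)
            n_pj += n_pj % 2
            d_cap = (np.pi / 2.0 * a / n_lat) * (2.0 * np.pi * rr / n_pj)
            for p in np.arange(n_pj) * (2.0 * np.pi / n_pj):
                c, s = np.cos(p), np.sin(p)
                pts.append([sign * xx, rr * c, rr * s])
                nrm.append([sign * np.sin(th), np.cos(th) * c, np.cos(th) * s])
                wts.append(d_cap)
    return SurfaceCloud(np.asarray(pts), np.asarray(wts), np.asarray(nrm))


def velocity_matrix(x: np.ndarray, sources: np.ndarray) -> np.ndarray:
    """Dense (3M, 3N) matrix mapping Stokeslet strengths (unit viscosity)
    to velocities at ``x``."""
    d = x[:, None, :] - sources[None, :, :]
    r2 = np.einsum("mni,mni->mn", d, d)
    r = np.sqrt(r2)
    r3 = r2 * r
    g = (
        np.eye(3)[None, None] / r[..., None, None]
        + d[..., :, None] * d[..., None, :] / r3[..., None, None]
    ) / _EIGHT_PI
    m, n = len(x), len(sources)
    return g.transpose(0, 2, 1, 3).reshape(3 * m, 3 * n)


def evaluate_velocity_and_gradient(
    x: np.ndarray,
    sources: np.ndarray,
    strengths: np.ndarray,
    *,
    chunk: int = 512,
    with_gradient: bool = True,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Velocity (M, 3) and velocity gradient (M, 3, 3) [i, k] = du_i/dx_k
    of the Stokeslet sum at points ``x`` (unit viscosity)."""
    m = len(x)
    u = np.empty((m, 3))
    gu = np.empty((m, 3, 3)) if with_gradient else None
    eye = np.eye(3)
    for s in range(0, m, chunk):
        xs = x[s : s + chunk]
        d = xs[:, None, :] - sources[None, :, :]
        r2 = np.einsum("mni,mni->mn", d, d)
        r = np.sqrt(r2)
        r3 = r2 * r
        fd = np.einsum("mni,ni->mn", d, strengths)
        u[s : s + chunk] = (
            strengths[None] / r[..., None] + d * (fd / r3)[..., None]
        ).sum(axis=1) / _EIGHT_PI
        if with_gradient:
            inv_r3 = 1.0 / r3
            g = (
                -np.einsum("ni,mnk->mik", strengths, d * inv_r3[..., None])
                + np.einsum("mni,nk->mik", d * inv_r3[..., None], strengths)
                + np.einsum("mn,ik->mik", fd * inv_r3, eye)
                - 3.0
                * np.einsum("mni,mnk->mik", d, d * (fd / (r3 * r2))[..., None])
            )
            gu[s : s + chunk] = g / _EIGHT_PI
    return u, gu


def evaluate_pressure(
    x: np.ndarray, sources: np.ndarray, strengths: np.ndarray, *, chunk: int = 2048
) -> np.ndarray:
    """Pressure (M,) of the Stokeslet sum at ``x`` (unit viscosity);
    ``p = f . d / (4 pi r^3)`` per source, zero mean constant."""
    m = len(x)
    p = np.empty(m)
    for s in range(0, m, chunk):
        d = x[s : s + chunk, None, :] - sources[None, :, :]
        r2 = np.einsum("mni,mni->mn", d, d)
        fd = np.einsum("mni,ni->mn", d, strengths)
        p[s : s + chunk] = (fd / (r2 * np.sqrt(r2))).sum(axis=1) / _FOUR_PI
    return p


def wall_traction(
    x: np.ndarray, normals: np.ndarray, sources: np.ndarray, strengths: np.ndarray
) -> np.ndarray:
    """Traction sigma . n (M, 3) at surface points ``x`` with unit normals
    ``normals`` (unit viscosity).  The Stokeslet stress is
    ``sigma_ij = -3 d_i d_j (f . d) / (4 pi r^5)``."""
    d = x[:, None, :] - sources[None, :, :]
    r2 = np.einsum("mni,mni->mn", d, d)
    r5 = r2**2 * np.sqrt(r2)
    fd = np.einsum("mni,ni->mn", d, strengths)
    dn = np.einsum("mni,mi->mn", d, normals)
    return (-3.0 / _FOUR_PI) * np.einsum("mn,mni->mi", dn * fd / r5, d)


class CollocationSystem:
    """Weighted no-slip collocation system with a reusable SVD factorisation,
    for problems that need several right-hand sides where later ones depend
    on earlier solutions (e.g. shape-derivative boundary conditions)."""

    def __init__(
        self,
        rotor_collocation: SurfaceCloud,
        rotor_sources: np.ndarray,
        wall_collocation: SurfaceCloud,
        wall_sources: np.ndarray,
        *,
        cond: float = 1e-12,
    ):
        self.rotor = rotor_collocation
        self.wall = wall_collocation
        self.sources = np.vstack([rotor_sources, wall_sources])
        self.n_rotor_sources = len(rotor_sources)
        self.points = np.vstack([rotor_collocation.points, wall_collocation.points])
        self.n_rotor = len(rotor_collocation)
        w = np.sqrt(
            np.concatenate([rotor_collocation.weights, wall_collocation.weights])
        )
        self.w3 = np.repeat(w / w.max(), 3)
        a = velocity_matrix(self.points, self.sources) * self.w3[:, None]
        u, s, vt = np.linalg.svd(a, full_matrices=False)
        keep = s > cond * s.max()
        self._u = u[:, keep]
        self._vs = vt[keep].T / s[keep]

    def solve_rotor_bc(self, rotor_velocity: np.ndarray) -> np.ndarray:
        """Stokeslet strengths (N, 3) for the BC ``u = rotor_velocity`` on
        the rotor and ``u = 0`` on the wall."""
        rhs = np.zeros((len(self.points), 3))
        rhs[: self.n_rotor] = rotor_velocity
        b = rhs.ravel() * self.w3
        return (self._vs @ (self._u.T @ b)).reshape(-1, 3)


@dataclass
class UnitStokesSolution:
    """Solution of the unit problem (viscosity 1, angular velocity 1).

    Strength columns: 0 = rigid rotation about z, 1 = unit x-translation of
    the rotor (auxiliary problem used for force diagnostics).
    """

    sources: np.ndarray
    strengths: np.ndarray  # (N, 3) rotation problem
    aux_strengths: np.ndarray  # (N, 3) unit x-translation problem
    n_rotor_sources: int
    rotor_surface: SurfaceCloud
    wall_surface: SurfaceCloud
    bc_residual_rod: float
    bc_residual_wall: float
    lstsq_rank: int = 0
    meta: dict = field(default_factory=dict)


def solve_unit_problem(
    rotor_collocation: SurfaceCloud,
    rotor_sources: np.ndarray,
    wall_collocation: SurfaceCloud,
    wall_sources: np.ndarray,
    *,
    cond: float = 1e-12,
) -> UnitStokesSolution:
    """Solve the no-slip collocation system for a rigid rotor spinning at
    unit angular velocity about z inside a fixed sphere (unit viscosity).

    The rotor boundary velocity is the rigid-body field ``omega_z x r``
    about the origin of the *lysosome*, which for an off-centre rotor
    corresponds to the steady co-rotating state of the rotor about the
    lysosome axis.  A second right-hand side (unit x-translation of the
    rotor) is solved simultaneously; it is required by the reciprocal-
    theorem force diagnostics and costs almost nothing extra.
    """
    x = np.vstack([rotor_collocation.points, wall_collocation.points])
    sources = np.vstack([rotor_sources, wall_sources])
    n_rotor = len(rotor_collocation)

    u_rot = np.zeros((len(x), 3))
    u_rot[:n_rotor] = np.cross([0.0, 0.0, 1.0], rotor_collocation.points)
    u_aux = np.zeros((len(x), 3))
    u_aux[:n_rotor, 0] = 1.0

    w = np.sqrt(np.concatenate([rotor_collocation.weights, wall_collocation.weights]))
    w = w / w.max()
    w3 = np.repeat(w, 3)

    a = velocity_matrix(x, sources) * w3[:, None]
    b = np.stack([u_rot.ravel() * w3, u_aux.ravel() * w3], axis=1)
    sol, _, rank, _ = lstsq(a, b, cond=cond, lapack_driver="gelsd")
    strengths = sol[:, 0].reshape(-1, 3)
    aux = sol[:, 1].reshape(-1, 3)

    # honest boundary-condition residuals at the collocation points,
    # normalised by the rotor tip speed
    resid = (a @ sol[:, 0] - b[:, 0]) / w3
    resid = np.linalg.norm(resid.reshape(-1, 3), axis=1)
    u_scale = np.linalg.norm(u_rot[:n_rotor], axis=1).max()
    bc_rod = float(resid[:n_rotor].max() / u_scale)
    bc_wall = float(resid[n_rotor:].max() / u_scale)

    return UnitStokesSolution(
        sources=sources,
        strengths=strengths,
        aux_strengths=aux,
        n_rotor_sources=len(rotor_sources),
        rotor_surface=rotor_collocation,
        wall_surface=wall_collocation,
        bc_residual_rod=bc_rod,
        bc_residual_wall=bc_wall,
        lstsq_rank=int(rank),
    )
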