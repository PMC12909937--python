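# Methods

`lysoflow` simulates the mechanical pathway by which rotating assemblies of
magnetic nanoparticles permeabilize the lysosomal membrane: dipolar
self-assembly under a rotating magnetic field (RMF), the Stokes flow the
spinning rod drives inside the organelle, the shear stress that flow exerts
on the membrane, and the mapping from that stress to a permeabilization
regime. This note records the models, the numerical choices, and what the
synthetic-data tests do and do not establish.

## Chain assembly model

A single particle is a cube of edge `a` (default 25 nm), mass density `rho`
(default 5180 kg/m^3, magnetite; the Zn-doped core density is not known
precisely and the value is configurable) and mass magnetization `M_s`
(default 69 A m^2/kg). Its saturated moment is `m = M_s rho a^3 =
5.585e-18 A m^2`. Particles chain head-to-tail; the attraction between
neighbours at centre spacing `s` is the point-dipole force
`F = 3 mu_0 m^2 / (2 pi s^4)` (~48 pN for touching cubes), multiplied by a
dimensionless `bond_strength_scale` that absorbs coating, misalignment and
thermal weakening and is the parameter the recovery machinery estimates.

The equilibrium chain under an RMF of amplitude `B` and frequency `f` is the
longest chain allowed by three caps:

1. **Geometry** — the rod must rotate freely inside the lysosome:
   `L <= fill_fraction * 2R` with `fill_fraction = 0.7` by default,
   reflecting electron-microscopy observations that assemblies stay clear
   of the membrane.
2. **Fragmentation** (Mason-number cap) — the hydrodynamic tension at the
   midpoint of a rotating rod, `c_perp eta omega L^2 / 8` with the
   transverse slender-body drag density `c_perp = 4 pi / (ln(L/d) + 0.84)`,
   snaps the chain when it exceeds the scaled bond force, giving
   `L_max = sqrt(8 k F / (c_perp eta omega))` (solved by fixed point in the
   logarithmic factor); `L_max ~ omega^-1/2`.
3. **Step-out** — synchronous rotation requires `m_tot B >= 2 pi f xi` with
   the end-over-end rotational drag `xi = pi eta L^3 / (3 (ln(L/d) -
   0.662))`. Below aspect ratio `exp(1/3 + 0.662) = 2.71` the slender-body
   expression degenerates (it is singular at `ln(L/d) = 0.662`), so the
   rotating-sphere coefficient `8 pi eta (L/2)^3` is used; the two agree
   exactly at the crossover, keeping the drag continuous and monotone.

Under the reference conditions (260 mT, 471.1 cP, R = 359.2 nm) the
fragmentation length at 1 Hz is ~8.3 um and the step-out frequency of the
geometry-capped 20-particle chain is ~175 Hz, so between 0.2 and 5 Hz the
geometric cap governs and the chain is a 500 nm rod at every experimental
frequency. The magnetization model is a fixed-magnitude moment locked to
the chain axis; the field exerts torque only (no gradient forces), and
Brownian rotation and chain flexibility are neglected.

## Stokes flow and wall shear

At organelle scale the Reynolds number is ~1e-7, so each rotation snapshot
is a steady incompressible Stokes problem: rigid-body velocity on the rod
surface, no slip on the spherical wall. The rod is modelled as a capsule
(cylinder with hemispherical caps) with diameter equal to the particle
edge; the cube-chain corrugation is below solver resolution. All fields are
exactly linear in angular velocity and viscosity, so one unit solve per
geometry is cached and rescaled — which also makes the linearity invariant
hold bit-tight for power-of-two frequency ratios.

The discretization is a method of fundamental solutions (Stokeslet
collocation): point-force singularities are placed *outside* the fluid (on
a shrunken capsule of radius 0.45 rod radii inside the rotor, tips stood
off by one rod radius, and on a sphere inflated to 1.55 R outside the
wall), and the no-slip conditions are enforced at quasi-uniform surface
collocation points in an area-weighted least-squares sense (truncated SVD /
`gelsd`). Because every Stokeslet satisfies the Stokes equations exactly,
the represented field is divergence-free to machine precision (measured
residual ~1e-14 against a 1e-8 tolerance) and velocity, pressure, velocity
gradients and tractions are evaluated analytically — there is no volume
mesh and no interpolation error.

Boundary accuracy is the one place the scheme is honest rather than
pretty: the wall velocity residual at default resolution is ~2e-3 of the
rod tip speed (tolerance 5e-3) and the rod-surface residual is ~3% rms with
a localized ~10-20% maximum at the cylinder-cap junction (tolerance 0.35
max-norm). Wall-side outputs are insensitive to this local defect, which is
demonstrated by the validation suite rather than asserted: against the
classical closed form for a solid sphere rotating inside a concentric
sphere (equatorial wall shear `3 eta Omega b^3 / (R^3 - b^3)`, torque
`8 pi eta Omega b^3 R^3 / (R^3 - b^3)`), the solver matches wall shear to
0.2% and torque to ~1e-8 at default resolution, and rod/wall torques (from
the source strengths and from an independent traction quadrature) balance
to better than 1e-8 against a 1% tolerance. The single `resolution` knob
scales the collocation density; wall shear changes by well under 1% between
resolutions 1.0 and 1.3 (capsule rotor: 0.5%).

Wall shear is reported as the magnitude of the tangential component of the
traction the fluid exerts on the membrane, maximized over the wall sample
points; `max_velocity` is the largest fluid speed on the sampled field,
which for a rigid rotor is the rod tip speed `omega L / 2` in the lab
frame. Reported torques are about the lysosome centre.

## Centering force

A rod displaced from the lysosome centre tumbles about its own centre (the
magnetic field prescribes torque, not position). The lateral force on it
splits into two parts with very different physics:

* The **quasi-static Stokes traction force**. Its component along the
  offset vanishes *identically* by kinematic reversibility — reflecting the
  geometry across the plane containing the offset and the rotation axis
  maps the problem onto itself with reversed rotation, while Stokes
  linearity requires the force to flip sign. Each rotation phase does carry
  an instantaneous transverse drift force (~1e-13 N at 50 nm offset), but
  the cycle average of the full vector is zero; the solver reproduces both
  statements to the discretization floor.
* The **first-order inertial (steady-streaming) correction**, the leading
  non-vanishing lateral force. Per rotation phase it is computed with the
  Lorentz reciprocal theorem, `F . e = -rho int (du/dt + u . grad u) . u_hat
  dV`, where `u_hat` is the auxiliary Stokes field for unit rod translation
  along the offset direction. The unsteady term is evaluated exactly via a
  shape-derivative boundary condition solved on the same collocation
  matrix (no finite differencing in time), and the volume integral uses a
  mirror-symmetric Gauss-Legendre x uniform-azimuth quadrature so that
  symmetry-forbidden components cancel instead of polluting the signal.
  The force is averaged over four rod orientations spanning half a turn
  (the rod is fore-aft symmetric, so the force is pi-periodic).

For the reference 20-particle rod at 1 Hz and 50 nm offset the
cycle-averaged inertial force is ~-1.6e-24 N along the offset — restoring.
The pressure built up where the tumbling rod approaches the membrane pushes
it back to the centre, consistent with the experimentally observed
self-centering of the assemblies; at zero offset the force vanishes to
~1e-10 of the offset-case value. The sign is kinematics-dependent: a rod
constrained to co-orbit the lysosome axis instead experiences a
Bernoulli-type attraction towards the near wall. Tumbling-in-place is the
default because torque-only actuation provides no centripetal constraint.
The fluid density default is 1100 kg/m^3 (protein-rich lysosomal lumen);
the force scale is ~1e-24 N, ten orders below the driving tractions, so it
matters for the migration direction, never for the flow fields.

## Viscometry

Molecular-rotor (DCVJ) fluorescence follows the Förster–Hoffmann power law
`I = k eta^x` over the calibration range. Calibration fits a straight line
in (log eta, log I) by ordinary least squares — the natural estimator under
the multiplicative noise of fluorescence — and inversion computes
`eta = (I/k)^(1/x)` with an extrapolation flag outside the calibrated
range. The measured two-point anchor (12-fold intensity increase from 40 cP
to 402 cP) pins the exponent at `ln 12 / ln(402/40) = 1.077`; the exponent
is data-determined, never assumed. The measured lysosomal viscosities
(90.1 cP untreated, 471.1 cP after particle loading) are treated as inputs
to the flow model, not as quantities this package re-derives.

## Permeabilization regimes

Wall shear maps to three regimes — sub-threshold, reversible LMP,
irreversible LMP — through two thresholds with half-open intervals closed
on the lower bound. No stress thresholds are measured directly; the
experiments constrain a *frequency* window (reversible at roughly 0.8-2 Hz,
irreversible at 5 Hz, inefficient at 0.2 Hz, stresses ~1 Pa). The defaults
are therefore calibrated, reproducibly and at run time, from the simulated
reference spectrum: `tau_low` = simulated peak shear at 0.8 Hz (~0.89 Pa),
`tau_high` = midpoint of the 2 Hz and 5 Hz values (~3.89 Pa). Outputs label
the thresholds as calibrated. Membrane elasticity, pore formation and the
kinetics of damage and repair are out of scope.

## Synthetic data and what the tests show

The generator emulates three measurement types with positivity-preserving
noise families: lognormal lysosome radii around the measured population
means (379 nm untreated, 439 nm loaded; the true dispersion is unpublished
and the default CV of 0.25 is an explicit placeholder), lognormal
multiplicative viscometry noise (default CV 0.10), and rounded-lognormal
chain-count noise (default dispersion 0.15). A single integer seed drives
`numpy.random.default_rng`; every table is byte-reproducible.

Bond-strength recovery inverts observed counts through the assembly model
by grid search on the squared-log-count loss. Because counts are integers
the loss is piecewise constant; the estimate is the geometric midpoint of
the arg-min interval and the reported uncertainty its half-width. The
default chain-count sweep (180/240/300/360 Hz) lies in the cohesion-limited
band where counts respond to the bond strength: at video-rate frequencies
(0.2-5 Hz) the geometric cap saturates all counts, the data carry no
signal, and `recover_bond_strength` raises an identifiability error rather
than returning a number. With the default noise and 200 observations the
truth is recovered to ~1.5% with a quantization-dominated uncertainty of
~4%.

Passing these tests shows the pipeline is self-consistent and invertible
under its own assumptions. It does not validate the assembly model against
real electron-microscopy counts (unavailable at reproducible precision),
does not test robustness to model misspecification (the generator and the
estimator share the assembly model), and says nothing about real radius or
count dispersions.

## Problem sizes and runtime

Default resolution places ~900 collocation points on the rod, ~1350 on the
wall, and ~1200 Stokeslet sources; a unit solve takes seconds to tens of
seconds on one core and is cached per geometry, so frequency sweeps with an
unchanged chain cost a single solve. The centering diagnostic solves four
phase geometries with three right-hand sides each plus an ~80k-point volume
quadrature; at the reduced resolution used for its sign-level checks it
runs in a few minutes. The synthetic recovery evaluates the assembly model
on an 801-point parameter grid in well under a minute.
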