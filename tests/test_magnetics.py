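"""Unit and property tests for the dipole-chain assembly model."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lysoflow as lf
from lysoflow.magnetics import (
    fragmentation_length,
    synchronous_phase_lag,
    transverse_drag_density,
)


class TestParticleMoment:
    def test_reference_value(self, particle):
        # 69 A m^2/kg * 5180 kg/m^3 * (25 nm)^3
        assert lf.particle_moment(particle) == pytest.approx(5.585e-18, rel=1e-3)

    def test_nonpositive_magnetization_rejected(self):
        with pytest.raises(lf.InvalidParameterError):
            lf.Nanoparticle(saturation_magnetization=0.0)

    def test_cubic_edge_scaling(self, particle):
        doubled = lf.Nanoparticle(edge_length=2 * particle.edge_length)
        assert lf.particle_moment(doubled) == pytest.approx(
            8.0 * lf.particle_moment(particle), rel=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        ms=st.floats(1.0, 200.0),
        rho=st.floats(1000.0, 9000.0),
    )
    def test_linear_in_magnetization_and_density(self, ms, rho):
        base = lf.Nanoparticle(saturation_magnetization=ms, mass_density=rho)
        scaled = lf.Nanoparticle(saturation_magnetization=2 * ms, mass_density=3 * rho)
        assert lf.particle_moment(scaled) == pytest.approx(
            6.0 * lf.particle_moment(base), rel=1e-12
        )


class TestDipoleBondForce:
    def test_reference_value(self, particle):
        # 3 mu0 m^2 / (2 pi s^4) at touching spacing
        assert lf.dipole_bond_force(particle) == pytest.approx(4.79e-11, rel=1e-3)

    def test_piconewton_scale(self, particle):
        # the actuation force scale expected for magnetic nanoparticles
        assert 1e-12 < lf.dipole_bond_force(particle) < 1e-9

    def test_inverse_quartic_spacing(self, particle):
        s = particle.spacing
        assert lf.dipole_bond_force(particle, 2 * s) == pytest.approx(
            lf.dipole_bond_force(particle, s) / 16.0, rel=1e-12
        )

    def test_interpenetrating_spacing_rejected(self, particle):
        with pytest.raises(lf.GeometryError):
            lf.dipole_bond_force(particle, 0.5 * particle.edge_length)


class TestRotationalDrag:
    def test_reference_value(self, particle):
        # pi eta L^3 / (3 (ln 10 - 0.662)) for a 10-particle chain in 471.1 cP
        chain = lf.ChainAssembly.assemble(particle, 10, 0.4711)
        assert lf.rotational_drag(chain, 0.4711) == pytest.approx(4.70e-21, rel=2e-3)

    def test_linear_in_viscosity(self, particle):
        chain = lf.ChainAssembly.assemble(particle, 10, 0.4711)
        assert lf.rotational_drag(chain, 0.9422) == pytest.approx(
            2.0 * lf.rotational_drag(chain, 0.4711), rel=1e-12
        )

    def test_sphere_fallback_for_compact_aspect(self, particle):
        # a one-particle "chain" has aspect ratio 1 and must use the
        # rotating-sphere coefficient 8 pi eta a^3 with a = L/2
        chain = lf.ChainAssembly.assemble(particle, 1, 0.1)
        expected = 8.0 * math.pi * 0.1 * (chain.length / 2.0) ** 3
        assert lf.rotational_drag(chain, 0.1) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(n1=st.integers(2, 15), extra=st.integers(1, 10))
    def test_monotone_in_length(self, particle, n1, extra):
        c1 = lf.ChainAssembly.assemble(particle, n1, 0.4711)
        c2 = lf.ChainAssembly.assemble(particle, n1 + extra, 0.4711)
        assert lf.rotational_drag(c2, 0.4711) > lf.rotational_drag(c1, 0.4711)


class TestStepOut:
    def test_reference_value(self, particle, field):
        chain = lf.ChainAssembly.assemble(particle, 10, 0.4711)
        f_so = lf.step_out_frequency(chain, field, 0.4711)
        assert f_so == pytest.approx(4.92e2, rel=2e-3)

    def test_vanishing_field(self, particle):
        chain = lf.ChainAssembly.assemble(particle, 10, 0.4711)
        weak = lf.RotatingField(amplitude=1e-12, frequency=1.0)
        assert lf.step_out_frequency(chain, weak, 0.4711) < 1e-6

    def test_phase_lag_at_step_out(self, particle):
        chain = lf.ChainAssembly.assemble(particle, 10, 0.4711)
        f_so = lf.step_out_frequency(chain, lf.RotatingField(0.26, 1.0), 0.4711)
        at_so = lf.RotatingField(0.26, f_so)
        assert synchronous_phase_lag(chain, at_so, 0.4711) == pytest.approx(
            math.pi / 2.0, rel=1e-9
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(k=st.floats(0.1, 10.0), n=st.integers(2, 20))
    def test_invariant_under_joint_moment_drag_scaling(self, particle, k, n):
        # m -> k m (via density) together with xi -> k xi (via viscosity)
        # leaves the step-out frequency unchanged
        field = lf.RotatingField(0.26, 1.0)
        base = lf.ChainAssembly.assemble(particle, n, 0.4711)
        scaled_p = lf.Nanoparticle(mass_density=particle.mass_density * k)
        scaled = lf.ChainAssembly.assemble(scaled_p, n, 0.4711 * k)
        assert lf.step_out_frequency(scaled, field, 0.4711 * k) == pytest.approx(
            lf.step_out_frequency(base, field, 0.4711), rel=1e-9
        )

    def test_reference_regime_far_from_step_out(
        self, particle, criteria, lysosome
    ):
        # at 260 mT the equilibrium chain follows the field comfortably at
        # every experimental frequency (synchronous rotation regime)
        for f in (0.2, 0.8, 1.0, 2.0, 5.0):
            rf = lf.RotatingField(0.26, f)
            chain = lf.equilibrium_chain(particle, criteria, rf, lysosome)
            assert lf.step_out_frequency(chain, rf, lysosome.viscosity) > 10.0 * f


class TestFragmentationLength:
    def test_static_field_never_fragments(self, particle, criteria):
        static = lf.RotatingField(0.26, 0.0)
        assert math.isinf(fragmentation_length(particle, criteria, static, 0.4711))

    def test_micron_scale_at_1hz(self, particle, criteria):
        # under reference conditions the stable length is micron-scale,
        # far above the lysosome, so geometry governs at low frequency
        L = fragmentation_length(particle, criteria, lf.RotatingField(0.26, 1.0), 0.4711)
        assert L == pytest.approx(8.27e-6, rel=0.01)

    def test_inverse_sqrt_frequency_scaling(self, particle, criteria):
        L1 = fragmentation_length(particle, criteria, lf.RotatingField(0.26, 1.0), 0.4711)
        L4 = fragmentation_length(particle, criteria, lf.RotatingField(0.26, 4.0), 0.4711)
        # exact omega^-1/2 up to the logarithmic drag-density correction
        assert L4 / L1 == pytest.approx(0.5, abs=0.05)

    def test_sqrt_bond_strength_scaling(self, particle, criteria):
        import dataclasses

        weak = dataclasses.replace(criteria, bond_strength_scale=0.5)
        L1 = fragmentation_length(particle, criteria, lf.RotatingField(0.26, 1.0), 0.4711)
        Lh = fragmentation_length(particle, weak, lf.RotatingField(0.26, 1.0), 0.4711)
        assert Lh / L1 == pytest.approx(1.0 / math.sqrt(2.0), abs=0.03)

    def test_transverse_drag_density_positive(self):
        assert transverse_drag_density(500e-9, 25e-9) > 0
        with pytest.raises(lf.GeometryError):
            transverse_drag_density(20e-9, 25e-9)


class TestEquilibriumChain:
    def test_reference_chain_is_geometry_capped(self, reference_chain, lysosome):
        # floor(0.7 * 2R / s) = 20 particles, 500 nm rod
        assert reference_chain.n_particles == 20
        assert reference_chain.length == pytest.approx(500e-9, rel=1e-9)
        assert reference_chain.length < lysosome.diameter

    def test_chain_length_identity(self, reference_chain):
        assert reference_chain.length == (
            reference_chain.n_particles * reference_chain.spacing
        )

    def test_nonincreasing_with_frequency(self, particle, criteria, lysosome):
        ns = [
            lf.equilibrium_chain(
                particle, criteria, lf.RotatingField(0.26, f), lysosome
            ).n_particles
            for f in (0.2, 0.8, 1.0, 2.0, 5.0)
        ]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_weak_bond_gives_strict_frequency_dependence(self, particle, lysosome):
        # with a weak enough bond the fragmentation cap beats the geometric
        # cap at 5 Hz and the chain shortens measurably
        weak = lf.AssemblyCriteria(bond_strength_scale=0.002)
        n_low = lf.equilibrium_chain(
            particle, weak, lf.RotatingField(0.26, 0.2), lysosome
        ).n_particles
        n_high = lf.equilibrium_chain(
            particle, weak, lf.RotatingField(0.26, 5.0), lysosome
        ).n_particles
        assert n_high < n_low

    def test_lysosome_smaller_than_particle_rejected(self, particle, criteria):
        tiny = lf.LysosomeGeometry(radius=10e-9, viscosity=0.4711)
        with pytest.raises(lf.GeometryError):
            lf.equilibrium_chain(particle, criteria, lf.RotatingField(0.26, 1.0), tiny)

    def test_zero_fill_fraction_rejected(self):
        with pytest.raises(lf.InvalidParameterError):
            lf.AssemblyCriteria(geometric_fill_fraction=0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        f1=st.floats(0.2, 400.0),
        df=st.floats(1.0, 400.0),
        kappa=st.floats(0.01, 2.0),
        visc=st.floats(0.05, 1.0),
    )
    def test_monotonicity_properties(self, particle, lysosome, f1, df, kappa, visc):
        """Chain length never grows with frequency or viscosity and never
        shrinks with field amplitude or bond strength."""
        crit = lf.AssemblyCriteria(bond_strength_scale=kappa)
        lys = lf.LysosomeGeometry(radius=lysosome.radius, viscosity=visc)
        n_a = lf.equilibrium_chain(
            particle, crit, lf.RotatingField(0.26, f1), lys
        ).n_particles
        n_b = lf.equilibrium_chain(
            particle, crit, lf.RotatingField(0.26, f1 + df), lys
        ).n_particles
        assert n_b <= n_a
        n_strong_field = lf.equilibrium_chain(
            particle, crit, lf.RotatingField(0.52, f1), lys
        ).n_particles
        assert n_strong_field >= n_a
        strong_bond = lf.AssemblyCriteria(bond_strength_scale=2.0 * kappa)
        n_strong_bond = lf.equilibrium_chain(
            particle, strong_bond, lf.RotatingField(0.26, f1), lys
        ).n_particles
        assert n_strong_bond >= n_a
        thick = lf.LysosomeGeometry(radius=lysosome.radius, viscosity=2.0 * visc)
        n_thick = lf.equilibrium_chain(
            particle, crit, lf.RotatingField(0.26, f1), thick
        ).n_particles
        assert n_thick <= n_a
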