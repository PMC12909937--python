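"""Tests of the intralysosomal Stokes solver against the closed-form
concentric-spheres solution and its physical invariants."""

import math

import numpy as np
import pytest

import lysoflow as lf


class TestOracle:
    def test_reference_closed_form_value(self, lysosome):
        # 3 eta Omega b^3 / (R^3 - b^3) at b = 200 nm, 1 Hz
        tau = lf.sphere_in_sphere_oracle(200e-9, lysosome, 2.0 * math.pi)
        assert tau == pytest.approx(1.853, rel=1e-3)

    def test_vanishing_rotor(self, lysosome):
        assert lf.sphere_in_sphere_oracle(1e-9, lysosome, 2.0 * math.pi) < 1e-6

    def test_linear_in_rotation_rate(self, lysosome):
        t1 = lf.sphere_in_sphere_oracle(200e-9, lysosome, 2.0 * math.pi)
        t2 = lf.sphere_in_sphere_oracle(200e-9, lysosome, 4.0 * math.pi)
        assert t2 == pytest.approx(2.0 * t1, rel=1e-14)

    def test_rotor_larger_than_lysosome_rejected(self, lysosome):
        with pytest.raises(lf.GeometryError):
            lf.sphere_in_sphere_oracle(400e-9, lysosome, 2.0 * math.pi)

    def test_velocity_profile_satisfies_boundaries(self, lysosome):
        flow = lf.ConcentricSpheresFlow(200e-9, lysosome.radius, lysosome.viscosity, 2.0 * math.pi)
        assert flow.azimuthal_velocity(200e-9) == pytest.approx(2.0 * math.pi * 200e-9, rel=1e-12)
        assert abs(flow.azimuthal_velocity(lysosome.radius)) < 1e-18


class TestNumericalVsOracle:
    def test_wall_shear_within_two_percent(self, sphere_solution, lysosome):
        exact = lf.sphere_in_sphere_oracle(200e-9, lysosome, 2.0 * math.pi)
        assert sphere_solution.max_wall_shear == pytest.approx(exact, rel=0.02)

    def test_rotor_torque_within_one_percent(self, sphere_solution, lysosome):
        flow = lf.ConcentricSpheresFlow(
            200e-9, lysosome.radius, lysosome.viscosity, 2.0 * math.pi
        )
        assert np.linalg.norm(sphere_solution.rod_torque) == pytest.approx(
            flow.rotor_torque_magnitude, rel=0.01
        )

    def test_sin_theta_shear_profile(self, sphere_solution, lysosome):
        flow = lf.ConcentricSpheresFlow(
            200e-9, lysosome.radius, lysosome.viscosity, 2.0 * math.pi
        )
        prof = lf.wall_shear_profile(sphere_solution)
        expected = flow.wall_shear(prof["theta_rad"].to_numpy())
        err = np.abs(prof["shear_pa"].to_numpy() - expected)
        assert err.max() <= 0.02 * flow.equatorial_wall_shear

    def test_mesh_convergence(self, lysosome):
        """Wall shear changes by <2% between the two finest default
        resolutions on the oracle geometry."""
        coarse = lf.solve_rotating_sphere(200e-9, lysosome, 2.0 * math.pi, resolution=1.0)
        fine = lf.solve_rotating_sphere(200e-9, lysosome, 2.0 * math.pi, resolution=1.3)
        assert fine.max_wall_shear == pytest.approx(coarse.max_wall_shear, rel=0.02)


class TestRodSolution:
    def test_zero_rotation_is_quiescent(self, lysosome, reference_chain):
        sol = lf.solve_rotating_rod(lysosome, reference_chain, 0.0)
        assert np.all(sol.velocity_field == 0.0)
        assert sol.max_wall_shear == 0.0
        assert sol.max_velocity == 0.0

    def test_divergence_free(self, rod_solution_1hz, sphere_solution):
        assert rod_solution_1hz.divergence_residual <= 1e-8
        assert sphere_solution.divergence_residual <= 1e-8

    def test_torque_balance(self, rod_solution_1hz, sphere_solution):
        assert rod_solution_1hz.torque_balance <= 0.01
        assert sphere_solution.torque_balance <= 0.01

    def test_rescaling_is_bit_tight(self, rod_solution_1hz):
        doubled = rod_solution_1hz.rescaled(2.0 * rod_solution_1hz.angular_velocity)
        assert doubled.max_wall_shear == 2.0 * rod_solution_1hz.max_wall_shear
        assert doubled.max_velocity == 2.0 * rod_solution_1hz.max_velocity
        assert np.array_equal(doubled.velocity_field, 2.0 * rod_solution_1hz.velocity_field)

    def test_linearity_in_viscosity(self, rod_solution_1hz, lysosome, reference_chain):
        thin = lf.LysosomeGeometry(radius=lysosome.radius, viscosity=lysosome.viscosity / 2.0)
        sol = lf.solve_rotating_rod(thin, reference_chain, 2.0 * math.pi)
        assert sol.max_wall_shear == pytest.approx(
            rod_solution_1hz.max_wall_shear / 2.0, rel=1e-12
        )
        # velocities are viscosity-independent in Stokes flow
        assert sol.max_velocity == pytest.approx(rod_solution_1hz.max_velocity, rel=1e-12)

    def test_max_velocity_is_tip_speed(self, rod_solution_1hz, reference_chain):
        tip = 2.0 * math.pi * reference_chain.length / 2.0
        assert rod_solution_1hz.max_velocity == pytest.approx(tip, rel=0.02)

    def test_rod_too_long_rejected(self, lysosome, particle):
        chain = lf.ChainAssembly.assemble(particle, 30, lysosome.viscosity)
        with pytest.raises(lf.GeometryError):
            lf.solve_rotating_rod(lysosome, chain, 2.0 * math.pi)

    def test_offset_out_of_bounds_rejected(self, lysosome, reference_chain):
        with pytest.raises(lf.GeometryError):
            lf.solve_rotating_rod(
                lysosome, reference_chain, 2.0 * math.pi, offset=(120e-9, 0, 0)
            )

    def test_centered_lateral_force_negligible(self, rod_solution_1hz):
        """Radial pressure symmetry at the centre: no net hydraulic force."""
        torque_scale = np.linalg.norm(rod_solution_1hz.rod_torque)
        force_scale = torque_scale / rod_solution_1hz.lysosome_radius
        assert np.linalg.norm(rod_solution_1hz.rod_force) < 1e-6 * force_scale


class TestWallShearProfile:
    def test_profile_max_matches_solution(self, rod_solution_1hz):
        prof = lf.wall_shear_profile(rod_solution_1hz)
        assert prof["shear_pa"].max() == rod_solution_1hz.max_wall_shear

    def test_centered_rod_max_in_equatorial_band(self, rod_solution_1hz):
        prof = lf.wall_shear_profile(rod_solution_1hz)
        theta_max = prof.loc[prof["shear_pa"].idxmax(), "theta_rad"]
        assert abs(theta_max - math.pi / 2.0) < math.radians(25)

    def test_offset_rod_max_near_tip(self, lysosome, particle):
        chain = lf.ChainAssembly.assemble(particle, 10, lysosome.viscosity)
        sol = lf.solve_rotating_rod(lysosome, chain, 2.0 * math.pi, offset=(80e-9, 0, 0))
        prof = lf.wall_shear_profile(sol)
        peak = prof.loc[prof["shear_pa"].idxmax()]
        # membrane region nearest the displaced rod tip (positive x side)
        assert peak["x_m"] > 0.5 * lysosome.radius
        centred = lf.solve_rotating_rod(lysosome, chain, 2.0 * math.pi)
        assert sol.max_wall_shear > centred.max_wall_shear


class TestShearSpectrum:
    def test_monotone_increase_with_frequency(self, reference_spectrum):
        t = reference_spectrum.table
        assert np.all(np.diff(t["max_wall_shear_pa"]) > 0)
        assert np.all(np.diff(t["max_velocity_m_s"]) > 0)

    def test_frequency_leverage(self, reference_spectrum):
        ratio = reference_spectrum.max_wall_shear_at(5.0) / reference_spectrum.max_wall_shear_at(0.2)
        assert ratio >= 2.0

    def test_fixed_chain_exactly_linear(
        self, particle, criteria, field, lysosome, reference_chain
    ):
        spec = lf.shear_spectrum(
            [1.0, 2.0, 4.0],
            particle,
            criteria,
            field,
            lysosome,
            chain=reference_chain,
        )
        tau = spec.table["max_wall_shear_pa"].to_numpy()
        assert tau[1] == 2.0 * tau[0]  # power-of-two rescale is exact
        assert tau[2] == 2.0 * tau[1]

    def test_unsorted_frequencies_rejected(self, particle, criteria, field, lysosome):
        with pytest.raises(lf.InvalidParameterError):
            lf.shear_spectrum([1.0, 0.5], particle, criteria, field, lysosome)

    def test_spectrum_roundtrip_csv(self, reference_spectrum, tmp_path):
        path = tmp_path / "spectrum.csv"
        reference_spectrum.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == (
            "frequency_hz,n_particles,chain_length_m,max_velocity_m_s,max_wall_shear_pa"
        )


class TestCenteringForce:
    def test_offset_force_is_restoring(self, offset_centering):
        assert offset_centering.along_offset < 0.0

    def test_centered_force_vanishes(self, centered_centering, offset_centering):
        assert np.linalg.norm(centered_centering.inertial) < 0.01 * np.linalg.norm(
            offset_centering.inertial
        )

    def test_mirrored_offset_mirrors_force(
        self, lysosome, reference_chain, offset_centering
    ):
        mirrored = lf.centering_force(
            lysosome,
            reference_chain,
            2.0 * math.pi,
            offset=(-50e-9, 0.0, 0.0),
            resolution=0.75,
            volume_grid=(28, 24, 40),
        )
        assert mirrored.inertial == pytest.approx(-offset_centering.inertial, rel=1e-6)
        # the projection on the offset direction is restoring on both sides
        assert mirrored.along_offset == pytest.approx(
            offset_centering.along_offset, rel=1e-6
        )

    def test_cycle_averaged_stokes_force_cancels(self, offset_centering):
        """Reversibility: the rotation-cycle average of the Stokes traction
        force is zero; what is left is far below the instantaneous
        transverse drift force (~1e-13 N at this geometry)."""
        assert np.linalg.norm(offset_centering.stokes) < 1e-14
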