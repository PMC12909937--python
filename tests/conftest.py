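"""Shared fixtures: the reference actuation conditions and (expensive)
flow solutions, solved once per session and reused."""

from __future__ import annotations

import math

import numpy as np
import pytest

import lysoflow as lf

#: reference conditions: 25 nm cubes at 69 emu/g, 260 mT field, lysosome
#: of radius 359.2 nm filled with 471.1 cP fluid
REFERENCE_FREQUENCIES = [0.2, 0.8, 1.0, 2.0, 5.0]


@pytest.fixture(scope="session")
def particle() -> lf.Nanoparticle:
    return lf.Nanoparticle()


@pytest.fixture(scope="session")
def criteria() -> lf.AssemblyCriteria:
    return lf.AssemblyCriteria()


@pytest.fixture(scope="session")
def field() -> lf.RotatingField:
    return lf.RotatingField(amplitude=0.26, frequency=1.0)


@pytest.fixture(scope="session")
def lysosome() -> lf.LysosomeGeometry:
    return lf.LysosomeGeometry()


@pytest.fixture(scope="session")
def reference_chain(particle, criteria, field, lysosome) -> lf.ChainAssembly:
    return lf.equilibrium_chain(particle, criteria, field, lysosome)


@pytest.fixture(scope="session")
def rod_solution_1hz(lysosome, reference_chain) -> lf.FlowSolution:
    """Centred equilibrium rod at 1 Hz, default resolution."""
    return lf.solve_rotating_rod(lysosome, reference_chain, 2.0 * math.pi)


@pytest.fixture(scope="session")
def sphere_solution(lysosome) -> lf.FlowSolution:
    """Spherical rotor (b = 200 nm) at 1 Hz: the oracle-comparison case."""
    return lf.solve_rotating_sphere(200e-9, lysosome, 2.0 * math.pi)


@pytest.fixture(scope="session")
def reference_spectrum(particle, criteria, field, lysosome) -> lf.ShearSpectrum:
    return lf.shear_spectrum(
        REFERENCE_FREQUENCIES, particle, criteria, field, lysosome
    )


@pytest.fixture(scope="session")
def thresholds() -> lf.RegimeThresholds:
    return lf.calibrate_thresholds()


@pytest.fixture(scope="session")
def offset_centering(lysosome, reference_chain):
    """Cycle-averaged centering force at +50 nm x-offset (reduced
    resolution; the assertions are sign- and ratio-level)."""
    return lf.centering_force(
        lysosome,
        reference_chain,
        2.0 * math.pi,
        offset=(50e-9, 0.0, 0.0),
        resolution=0.75,
        volume_grid=(28, 24, 40),
    )


@pytest.fixture(scope="session")
def centered_centering(lysosome, reference_chain):
    return lf.centering_force(
        lysosome,
        reference_chain,
        2.0 * math.pi,
        offset=(0.0, 0.0, 0.0),
        resolution=0.75,
        volume_grid=(28, 24, 40),
    )
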