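"""Shared fixtures: coarse femur models and a session-wide benchmark run.

Meshes are deliberately coarse (8 mm test mesh, 7 mm benchmark mesh) so the
whole suite runs in a few minutes on one CPU; the acceptance script uses the
default 4 mm resolution.
"""

import numpy as np
import pytest
from hypothesis import settings

from femurbench import FemurParams, generate_femur, generate_stance_loads
from femurbench.fe import assemble
from femurbench.materials import bin_materials
from femurbench.runner import run_benchmark, solve_method

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")

COARSE = 8.0  # mm edge length for unit-test meshes
BENCH = 7.0  # mm edge length for the ordering benchmark


@pytest.fixture(scope="session")
def femur():
    return generate_femur(FemurParams(target_edge_length=COARSE))


@pytest.fixture(scope="session")
def materials(femur):
    return bin_materials(femur)


@pytest.fixture(scope="session")
def loadcase(femur):
    return generate_stance_loads(femur)


@pytest.fixture(scope="session")
def system(femur, materials):
    return assemble(femur, materials)


@pytest.fixture(scope="session")
def solved(femur, materials, loadcase, system):
    """Solve every boundary-condition method once on the coarse femur."""
    from femurbench.constraints import METHOD_NAMES

    out = {}
    for method in METHOD_NAMES:
        out[method] = solve_method(
            femur, materials, loadcase, method, system=system
        )
    return out


@pytest.fixture(scope="session")
def benchmark():
    """Full 5-geometry x 6-method benchmark at the test resolution."""
    return run_benchmark(FemurParams(target_edge_length=BENCH))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
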