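"""Shared fixtures: toy assemblies and the full study structures.

Heavy builds (the four rings, the 3PS tile, the buckyball) are session-scoped
so geometry, coarse-graining and acceptance tests share one pipeline run per
structure.
"""

import numpy as np
import pytest

from dnanma import RunConfig, coarse_grain, get_design, run_pipeline
from dnanma.builder import build_assembly
from dnanma.fixtures import generate_fixture


@pytest.fixture(scope="session")
def toy_fixtures():
    return {q: generate_fixture(f"toy_ring_c{q}") for q in (3, 4, 6)}


@pytest.fixture(scope="session")
def dimer():
    return generate_fixture("dimer")


@pytest.fixture(scope="session")
def mini_ball():
    return generate_fixture("mini_ball")


def _run(design, n_modes=16, method="auto"):
    return run_pipeline(RunConfig(design=design, n_modes=n_modes,
                                  method=method))


@pytest.fixture(scope="session")
def r1c_run():
    return _run("r1c")


@pytest.fixture(scope="session")
def r1o_run():
    return _run("r1o")


@pytest.fixture(scope="session")
def r2c_run():
    return _run("r2c")


@pytest.fixture(scope="session")
def r2o_run():
    return _run("r2o")


@pytest.fixture(scope="session")
def tile_run():
    return _run("tile", n_modes=18)


@pytest.fixture(scope="session")
def bucky_run():
    return _run("buckyball", n_modes=14, method="scenm")


@pytest.fixture(scope="session")
def r1c_model(r1c_run):
    return r1c_run["model"]


@pytest.fixture(scope="session")
def r1c_cg(r1c_run):
    return r1c_run["cg"]


@pytest.fixture(scope="session")
def bucky_model(bucky_run):
    return bucky_run["model"]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180627)
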