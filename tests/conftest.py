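"""Shared fixtures: a reduced-size synthetic leaf section and one converged
baseline solve, both session-scoped because steady-state PDE solves are the
expensive step of this suite."""

from __future__ import annotations

import numpy as np
import pytest

from leafgas import (
    Environment,
    GeometryGenParams,
    TransportProps,
    generate_leaf_microstructure,
    load_fvcb_params,
    mesh,
    run_condition,
)
from leafgas.synthetic import default_j_response

#: reduced-width test section (same thickness and morphology targets as the
#: default, fewer cells) — keeps one steady solve at a few seconds
TEST_GEOM_KW = dict(width_um=60.0, n_cells=26, bundle_radius_um=12.0)


@pytest.fixture(scope="session")
def fvcb():
    return load_fvcb_params("highN_flowering")


@pytest.fixture(scope="session")
def j_1000(fvcb):
    return default_j_response(1000.0, fvcb.s)


@pytest.fixture(scope="session")
def baseline_env(j_1000):
    return Environment(ca=350.0, o2_mbar=210.0, iinc=1000.0, j=j_1000)


@pytest.fixture(scope="session")
def small_geometry():
    return generate_leaf_microstructure(GeometryGenParams(seed=0, **TEST_GEOM_KW))


@pytest.fixture(scope="session")
def small_mesh(small_geometry):
    return mesh(small_geometry, 0.5)


@pytest.fixture(scope="session")
def baseline_run(small_mesh, fvcb, baseline_env):
    """(field, summary) of the baseline condition on the test section."""
    return run_condition(small_mesh, TransportProps(), fvcb, baseline_env)


CA_TEST_LIST = (50.0, 150.0, 350.0, 650.0, 1500.0)


@pytest.fixture(scope="session")
def co2_curve_21(small_mesh, fvcb, baseline_env):
    from leafgas import co2_response_curve

    return co2_response_curve(
        small_mesh, TransportProps(), fvcb, baseline_env, CA_TEST_LIST
    )


@pytest.fixture(scope="session")
def co2_curve_2pct(small_mesh, fvcb, j_1000):
    from leafgas import co2_response_curve

    env = Environment(ca=350.0, o2_mbar=20.0, iinc=1000.0, j=j_1000)
    return co2_response_curve(
        small_mesh, TransportProps(), fvcb, env, (150.0, 350.0, 650.0)
    )
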