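import numpy as np
import pytest

from coopdiscern import (
    SimulationGrid,
    build_database,
    default_doses,
    default_times,
    lhs_scan,
)


@pytest.fixture(scope="session")
def small_db():
    """A small manifold database (envelope thresholds) for stage-logic tests."""
    return build_database(lhs_scan(200, seed=1))


@pytest.fixture(scope="session")
def wide_det_grid():
    """Deterministic grid over the full scanned dose range."""
    return SimulationGrid(default_doses(60, 1e-3, 1e8), default_times(50))


@pytest.fixture(scope="session")
def assay_grid():
    """The benchmark assay layout: 20 doses over [1e-3, 1e7], 50 times."""
    return SimulationGrid(default_doses(20, 1e-3, 1e7), default_times(50))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
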