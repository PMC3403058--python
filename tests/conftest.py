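import numpy as np
import pytest

from cyclesync import (table1, table1_coupling, draw_initial_conditions,
                       integrate_deterministic)


@pytest.fixture(scope="session")
def params():
    return table1()


@pytest.fixture(scope="session")
def coupling():
    return table1_coupling()


@pytest.fixture(scope="session")
def coupled_traj(params, coupling):
    """One synchronized Table-1 trajectory shared across tests."""
    x0 = draw_initial_conditions(coupling, seed=42)
    return integrate_deterministic(params, coupling, params.alpha1, x0,
                                   300.0, dt_out=0.01)


@pytest.fixture(scope="session")
def single_traj(params):
    x0 = np.random.default_rng(1).uniform(0, 1, 3)
    return integrate_deterministic(params, None, params.alpha1, x0,
                                   120.0, dt_out=0.002)
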