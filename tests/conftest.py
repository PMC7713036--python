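import numpy as np
import pytest

import stochmsm as sm
from stochmsm import _engine


@pytest.fixture(scope="session")
def tiny():
    return sm.tiny_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """2,000-subject cohort under the reference confounded DGP (rescaled rate)."""
    return sm.simulate_cohort(sm.scaled_config(2_000, seed=1))


@pytest.fixture(scope="session")
def small_arrays(small_cohort):
    return _engine.panel_arrays_from_cohort(small_cohort)


@pytest.fixture(scope="session")
def default_cohort():
    """20,000-subject cohort under the reference confounded DGP."""
    return sm.simulate_cohort(sm.DGPConfig(seed=1))


@pytest.fixture(scope="session")
def default_arrays(default_cohort):
    return _engine.panel_arrays_from_cohort(default_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
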