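import numpy as np
import pytest

from chemorad import make_params
from chemorad.params import SCENARIOS


@pytest.fixture(scope="session")
def default_params():
    return make_params()


@pytest.fixture(scope="session")
def tumor_free_params():
    """Slow-tumor-growth scenario with a stable tumor-free state."""
    return make_params(SCENARIOS["tumor-free"])


@pytest.fixture(scope="session")
def endemic_params():
    """Slow-normal-growth scenario with a stable coexistence state."""
    return make_params(SCENARIOS["endemic"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
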