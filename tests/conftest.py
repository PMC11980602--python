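import numpy as np
import pytest

from defdyn.config import SimConfig
from defdyn.simulate import simulate


@pytest.fixture(scope="session")
def sim_out():
    """A small but complete simulated dataset shared across tests."""
    return simulate(SimConfig(n_months=36, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
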