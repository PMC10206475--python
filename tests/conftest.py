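import numpy as np
import pytest

from matrinet import SimulationConfig, simulate_dataset
from matrinet.pipeline import build_context


@pytest.fixture(scope="session")
def default_data():
    """The default synthetic troop dataset (seed 0): the study conditions."""
    return simulate_dataset(SimulationConfig(rng_seed=0))


@pytest.fixture(scope="session")
def default_ctx(default_data):
    return build_context(default_data)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
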