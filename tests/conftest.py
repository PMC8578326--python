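import numpy as np
import pytest
from hypothesis import settings

from lotra import EmbeddingParams, delay_embed, distance_matrix, sine_series

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sine():
    """The 300-point benchmark sine wave."""
    return sine_series()


@pytest.fixture(scope="session")
def sine_t15_distances(sine):
    """Distance matrix of the benchmark sine embedded at t=15, m=2."""
    traj = delay_embed(sine, EmbeddingParams(delay=15, dimension=2))
    return distance_matrix(traj)
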