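import numpy as np
import pytest

from bndd.gp import ObservedData, OptimizerConfig
from bndd.kernels import Partition


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_config():
    """Small-restart optimiser settings to keep unit tests quick."""
    return OptimizerConfig(n_restarts=2, seed=0)


@pytest.fixture
def small_rd_data(rng):
    """Six random points with a jump of 2 at x0 = 0."""
    x = np.sort(rng.uniform(-1, 1, 24))
    y = 0.5 * x + 2.0 * (x >= 0) + rng.normal(0, 0.3, x.size)
    return ObservedData(x, y, partition=Partition(threshold=0.0))


@pytest.fixture
def tiny_data(rng):
    x = rng.uniform(-1, 1, 6)
    y = rng.normal(0, 1, 6)
    return ObservedData(x, y)
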