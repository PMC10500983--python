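import numpy as np
import pytest

import mugrid as mg
from mugrid.decomposition import decompose
from mugrid.synthesis import validation_recording


@pytest.fixture(scope="session")
def pool200():
    """Default 200-unit anatomical pool."""
    return mg.build_pool(count=200, seed=11)


@pytest.fixture(scope="session")
def small_pool():
    """Small pool for fast forward-model tests."""
    return mg.build_pool(count=12, seed=3)


@pytest.fixture(scope="session")
def small_muaps(small_pool):
    grid = mg.simulated_grid(6, 8)
    return mg.compute_muaps(small_pool, grid, fiber_subsample=60, seed=4)


@pytest.fixture(scope="session")
def benchmark_emg():
    """Ground-truth 15-unit, 64-channel benchmark recording (~30 s, 20 dB)."""
    return validation_recording(seed=5)


@pytest.fixture(scope="session")
def benchmark_decomposition(benchmark_emg):
    """Full decomposition of the benchmark recording (shared: it is the
    expensive stage several behavioural tests inspect)."""
    return decompose(benchmark_emg, mode="whole")


def rng(seed=0):
    return np.random.default_rng(seed)
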