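import numpy as np
import pytest

from ssgrn.gapso import GAPSOConfig
from ssgrn.synthetic import BenchmarkSpec, generate_benchmark


@pytest.fixture(scope="session")
def bench3():
    """Noise-free 3-gene benchmark (network + one clean time series)."""
    spec = BenchmarkSpec(n_genes=3, noise_sd=0.0, seed=2)
    model, datasets = generate_benchmark(spec)
    return model, datasets[0]


@pytest.fixture()
def tiny_cfg():
    """Small optimizer settings for fast structural tests."""
    return GAPSOConfig(pop_size=20, max_iterations=8, seed=5)


class PinnedRng:
    """Duck-typed stand-in for RngStream returning a fixed uniform value."""

    def __init__(self, value: float):
        self.value = float(value)

    def uniform(self, low=0.0, high=1.0, size=None):
        if size is None:
            return low + (high - low) * self.value
        return np.full(size, low + (high - low) * self.value)

    def integers(self, low, high, size=None):
        return np.full(size if size is not None else 1, low, dtype=int)

    def choice(self, n, size, replace=True):
        return np.zeros(size, dtype=int)


@pytest.fixture()
def pinned_rng():
    return PinnedRng
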