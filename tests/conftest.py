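import numpy as np
import pytest

from fcdbn import TimeSeriesDataset, make_benchmark_suite, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """Deterministic 3-gene, 10-point dataset with one true edge 0 -> 1."""
    rng = np.random.default_rng(7)
    G, T = 3, 10
    x = np.empty((G, T))
    x[:, 0] = rng.standard_normal(G)
    for t in range(1, T):
        x[0, t] = 0.2 * x[0, t - 1] + 0.3 * rng.standard_normal()
        x[1, t] = 0.8 * x[0, t - 1] + 0.3 * rng.standard_normal()
        x[2, t] = 0.3 * rng.standard_normal()
    return TimeSeriesDataset(x, ("a", "b", "c"))


@pytest.fixture
def yeast_like():
    data, truth = simulate(make_benchmark_suite("yeast_like")[0])
    return data, truth
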