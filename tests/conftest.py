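import numpy as np
import pytest

from psntopo.psn import PatientGraph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle_graph():
    """Unweighted (all weights 1) triangle."""
    W = np.ones((3, 3)) - np.eye(3)
    return PatientGraph(W, 1.0, ["a", "b", "c"])


@pytest.fixture
def two_clique_graph():
    """Two equal 15-node cliques (weight 0.9) joined by weak 0.05 edges."""
    n = 30
    W = np.full((n, n), 0.05)
    W[:15, :15] = 0.9
    W[15:, 15:] = 0.9
    np.fill_diagonal(W, 0.0)
    return PatientGraph(W, 2.0, [f"s{i:02d}" for i in range(n)])


def random_graph(rng, n, low=0.05, high=1.0):
    W = rng.uniform(low, high, (n, n))
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return PatientGraph(W, 2.0, [f"s{i}" for i in range(n)])
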