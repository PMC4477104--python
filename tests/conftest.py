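import numpy as np
import pytest

from fcgraph.connectivity import ThresholdedNetwork


def net_from_weights(w: np.ndarray, sparsity: float = 0.5) -> ThresholdedNetwork:
    w = np.asarray(w, dtype=float)
    k = int((w > 0).sum() // 2)
    return ThresholdedNetwork(w, sparsity, k)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def k4():
    """Complete unit-weight graph on 4 nodes."""
    w = np.ones((4, 4)) - np.eye(4)
    return net_from_weights(w)


@pytest.fixture
def star5():
    """Star with center 0 and four leaves."""
    w = np.zeros((5, 5))
    w[0, 1:] = 1.0
    w[1:, 0] = 1.0
    return net_from_weights(w)


@pytest.fixture
def path3():
    """Path A-B-C with unit weights."""
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[1, 2] = w[2, 1] = 1.0
    return net_from_weights(w)


def ring_lattice(n: int = 50, k: int = 4,
                 rng: np.random.Generator | None = None) -> ThresholdedNetwork:
    """Watts-Strogatz substrate: each node tied to k nearest neighbours."""
    w = np.zeros((n, n))
    for i in range(n):
        for d in range(1, k // 2 + 1):
            j = (i + d) % n
            val = 1.0 if rng is None else rng.uniform(0.5, 1.0)
            w[i, j] = w[j, i] = val
    return net_from_weights(w)
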