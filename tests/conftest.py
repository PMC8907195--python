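import numpy as np
import pytest

from periconn.adjacency import WeightedAdjacency


def labels(n):
    return tuple(f"R{i:02d}" for i in range(n))


def adjacency_from_edges(n, edges):
    """Build a WeightedAdjacency from (i, j, w) triples."""
    w = np.zeros((n, n))
    for i, j, val in edges:
        w[i, j] = w[j, i] = val
    return WeightedAdjacency(labels(n), w)


def random_adjacency(rng, n, p=0.5, weighted=True, zero_diag=True):
    """Random symmetric non-negative test matrix."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(iu[0].size) < p
    vals = rng.lognormal(1.0, 0.7, iu[0].size) if weighted else np.ones(iu[0].size)
    w[iu] = mask * vals
    w = w + w.T
    if not zero_diag:
        w = w + np.diag(rng.lognormal(1.0, 0.7, n))
    return WeightedAdjacency(labels(n), w)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def path_graph_3():
    # A - B - C with unit weights
    return adjacency_from_edges(3, [(0, 1, 1.0), (1, 2, 1.0)])


@pytest.fixture
def star_5():
    # center 0 with 4 leaves, unit weights
    return adjacency_from_edges(5, [(0, i, 1.0) for i in range(1, 5)])


@pytest.fixture
def triangle():
    return adjacency_from_edges(3, [(0, 1, 1.0), (0, 2, 1.0), (1, 2, 1.0)])
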