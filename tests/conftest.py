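import numpy as np
import pytest

from dynmod.synthgen import SystemAtlas


def two_cliques_adjacency(n_per: int = 4) -> np.ndarray:
    """Two disconnected cliques with unit weights."""
    n = 2 * n_per
    A = np.zeros((n, n))
    for start in (0, n_per):
        block = slice(start, start + n_per)
        A[block, block] = 1.0
    np.fill_diagonal(A, 0.0)
    return A


def random_adjacency(rng: np.random.Generator, n: int,
                     density: float = 0.6) -> np.ndarray:
    """Random symmetric nonnegative weighted graph with zero diagonal."""
    upper = rng.random((n, n)) * (rng.random((n, n)) < density)
    A = np.triu(upper, k=1)
    A = A + A.T
    if A.sum() == 0:  # ensure a non-empty graph
        A[0, 1] = A[1, 0] = 1.0
    return A


@pytest.fixture
def two_clique_graph():
    return two_cliques_adjacency(4)


@pytest.fixture
def atlas24():
    return SystemAtlas.equal_systems(24, 4)
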