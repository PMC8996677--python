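import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


def random_adjacency(rng, n=None, density=None):
    """A random symmetric binary adjacency with zero diagonal."""
    n = n or int(rng.integers(4, 13))
    density = density if density is not None else rng.uniform(0.1, 0.9)
    A = np.zeros((n, n), dtype=int)
    iu = np.triu_indices(n, 1)
    mask = rng.random(iu[0].size) < density
    A[iu[0][mask], iu[1][mask]] = 1
    A = A + A.T
    return A


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def graph_factory():
    return random_adjacency


def complete_graph(n):
    A = np.ones((n, n), dtype=int)
    np.fill_diagonal(A, 0)
    return A


def star_graph(n_leaves):
    n = n_leaves + 1
    A = np.zeros((n, n), dtype=int)
    A[0, 1:] = 1
    A[1:, 0] = 1
    return A


def path_graph(n):
    A = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        A[i, i + 1] = A[i + 1, i] = 1
    return A
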