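import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from cmcnet.graphio import Network


def net_from_edges(edges, n):
    A = np.zeros((n, n))
    for i, j in edges:
        A[i, j] = A[j, i] = 1.0
    return Network(A, tuple(str(i) for i in range(n)))


@pytest.fixture
def p3():
    """Path 0-1-2."""
    return net_from_edges([(0, 1), (1, 2)], 3)


@pytest.fixture
def k2():
    return Network(np.array([[0.0, 1.0], [1.0, 0.0]]), ("a", "b"))


@pytest.fixture
def k3():
    return net_from_edges([(0, 1), (1, 2), (0, 2)], 3)


@pytest.fixture
def k4():
    return net_from_edges([(i, j) for i in range(4) for j in range(i + 1, 4)], 4)


@pytest.fixture
def c4():
    return net_from_edges([(0, 1), (1, 2), (2, 3), (3, 0)], 4)


@pytest.fixture
def star3():
    """K_{1,3}: hub 0, leaves 1-3."""
    return net_from_edges([(0, 1), (0, 2), (0, 3)], 4)


@pytest.fixture
def two_triangles():
    """Two triangles joined by a single edge (6 nodes)."""
    return net_from_edges(
        [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)], 6
    )
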