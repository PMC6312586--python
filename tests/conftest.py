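import numpy as np
import pytest

from plitree.bands import THETA
from plitree.connectivity import ConnectivityMatrix
from plitree.mst import TreeGraph
from plitree.recording import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone_recording():
    """Two 6-Hz sinusoids, the second lagging by pi/4, 8 s at 512 Hz."""
    fs = 512.0
    t = np.arange(int(8 * fs)) / fs
    data = np.vstack(
        [np.cos(2 * np.pi * 6 * t), np.cos(2 * np.pi * 6 * t - np.pi / 4)]
    )
    return Recording(data=data, fs=fs, labels=("a", "b"))


@pytest.fixture
def star4():
    """Star tree on 4 nodes, centre node 0."""
    return TreeGraph(n_nodes=4, edges=[(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)])


@pytest.fixture
def path4():
    return TreeGraph(n_nodes=4, edges=[(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)])


@pytest.fixture
def path5():
    return TreeGraph(
        n_nodes=5, edges=[(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (3, 4, 1.0)]
    )


def random_tree(n: int, rng: np.random.Generator) -> TreeGraph:
    """Uniform random labelled tree via a random Pruefer sequence."""
    if n == 2:
        return TreeGraph(n_nodes=2, edges=[(0, 1, 1.0)])
    prufer = rng.integers(0, n, size=n - 2)
    edges = [(min(i, j), max(i, j), 1.0) for i, j in prufer_to_edges(prufer, n)]
    return TreeGraph(n_nodes=n, edges=edges)


def prufer_to_edges(prufer, n):
    degree = np.ones(n, dtype=int)
    for x in prufer:
        degree[x] += 1
    edges = []
    for x in prufer:
        for leaf in range(n):
            if degree[leaf] == 1:
                edges.append((leaf, int(x)))
                degree[leaf] -= 1
                degree[x] -= 1
                break
    last = [i for i in range(n) if degree[i] == 1]
    edges.append((last[0], last[1]))
    return edges


def random_pli_matrix(n: int, rng: np.random.Generator) -> ConnectivityMatrix:
    v = rng.uniform(0.05, 1.0, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return ConnectivityMatrix(values=v, band=THETA)
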