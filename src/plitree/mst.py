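"""Minimum spanning tree construction and tree topology metrics.

The MST is built with Kruskal's algorithm on edge weights 1/PLI, so the
strongest functional connections are retained: edges are ranked in ascending
weight and added one at a time, discarding any edge that would close a loop,
until all N nodes are connected by M = N - 1 links.

Global metrics: leaf fraction (share of degree-1 nodes), degree divergence
kappa = <k^2>/<k> (broadness of the degree distribution), and tree hierarchy
Th = L / (2 M BC_max), which balances network integration (many leaves)
against hub overload (large maximum betweenness).  Nodal metrics: degree,
betweenness centrality normalised by (N-1)(N-2)/2, and hop-count
eccentricity.  After construction the tree is treated as unweighted, as is
conventional in MST analyses of M/EEG networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .errors import InvalidInputError, UndefinedMetricError

GLOBAL_METRICS = ("leaf_fraction", "degree_divergence", "tree_hierarchy")
NODAL_METRICS = ("degree", "betweenness", "eccentricity")


@dataclass
class TreeGraph:
    """A spanning tree: N nodes, N-1 edges of the form (i, j, weight)."""

    n_nodes: int
    edges: list[tuple[int, int, float]]
    labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if len(self.edges) != self.n_nodes - 1:
            raise InvalidInputError(
                f"a spanning tree on {self.n_nodes} nodes needs "
                f"{self.n_nodes - 1} edges, got {len(self.edges)}"
            )
        if not self.labels:
            self.labels = tuple(f"ch{i}" for i in range(self.n_nodes))
        self.labels = tuple(self.labels)
        g = self.to_networkx()
        if g.number_of_nodes() != self.n_nodes or not nx.is_connected(g):
            raise InvalidInputError("edge list does not span all nodes")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(self.edges)
        return g

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_mst(mat: ConnectivityMatrix) -> TreeGraph:
    """Kruskal's MST on weights 1/PLI.

    PLI = 0 entries receive a deterministic sentinel weight one order of
    magnitude above the largest finite 1/PLI in the matrix, so fully
    unsynchronised pairs are used only as a last resort and the result stays
    deterministic on degenerate inputs.  Ties are broken by ascending
    (min(i, j), max(i, j)).
    """
    v = mat.values
    n = mat.n_nodes
    if n < 2:
        raise InvalidInputError("need at least 2 nodes to build a spanning tree")
    if not np.allclose(v, v.T, atol=1e-12):
        raise InvalidInputError("connectivity matrix must be symmetric")
    iu, ju = np.triu_indices(n, k=1)
    pli = v[iu, ju]
    if np.any(pli < 0):
        raise InvalidInputError("PLI entries must be nonnegative")
    with np.errstate(divide="ignore"):
        w = np.where(pli > 0, 1.0 / np.where(pli > 0, pli, 1.0), np.inf)
    finite = w[np.isfinite(w)]
    sentinel = 10.0 * finite.max() if finite.size else 1.0
    w = np.where(np.isfinite(w), w, sentinel)
    order = np.lexsort((ju, iu, w))
    uf = _UnionFind(n)
    edges: list[tuple[int, int, float]] = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if uf.union(i, j):
            edges.append((i, j, float(w[k])))
            if len(edges) == n - 1:
                break
    return TreeGraph(n_nodes=n, edges=edges, labels=mat.labels)


def leaf_fraction(t: TreeGraph) -> float:
    """Fraction of nodes with degree 1."""
    deg = t.degrees()
    return float(np.mean(deg == 1))


def degree_divergence(t: TreeGraph) -> float:
    """kappa = <k^2> / <k> over the tree's degree sequence."""
    deg = t.degrees().astype(float)
    return float(np.mean(deg**2) / np.mean(deg))


def _adjacency(t: TreeGraph) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(t.n_nodes)]
    for i, j, _ in t.edges:
        adj[i].append(j)
        adj[j].append(i)
    return adj


def _dfs_order(adj: list[list[int]], root: int = 0) -> tuple[list[int], list[int]]:
    """Preorder node list and parent array of the tree rooted at ``root``."""
    n = len(adj)
    parent = [-1] * n
    order = []
    stack = [root]
    parent[root] = root
    while stack:
        v = stack.pop()
        order.append(v)
        for u in adj[v]:
            if parent[u] == -1:
                parent[u] = v
                stack.append(u)
    return order, parent


def betweenness(t: TreeGraph) -> np.ndarray:
    """Normalised betweenness centrality per node.

    For node v: the number of unordered node pairs whose (unique) tree path
    has v as an interior vertex, divided by (N-1)(N-2)/2.  In a tree this
    is a subtree-size computation: removing v splits the remaining N-1
    nodes into components of sizes s_1..s_k, and the pairs routed through
    v are C(N-1, 2) minus the within-component pairs.
    """
    n = t.n_nodes
    adj = _adjacency(t)
    order, parent = _dfs_order(adj)
    size = np.ones(n, dtype=np.int64)
    for v in reversed(order):
        if parent[v] != v:
            size[parent[v]] += size[v]

    def c2(x):
        return x * (x - 1) // 2

    total = c2(n - 1)
    bc = np.empty(n, dtype=float)
    for v in range(n):
        within = 0
        child_sum = 0
        for u in adj[v]:
            s = size[u] if parent[u] == v else n - size[v]
            within += c2(s)
            child_sum += s
        bc[v] = (total - within) / total if total else 0.0
    return bc


def eccentricity(t: TreeGraph) -> np.ndarray:
    """Hop-count eccentricity per node (tree treated as unweighted).

    In a tree every node's farthest vertex is an endpoint of a diameter, so
    three breadth-first searches suffice.
    """
    adj = _adjacency(t)

    def bfs(src: int) -> np.ndarray:
        dist = np.full(t.n_nodes, -1, dtype=int)
        dist[src] = 0
        frontier = [src]
        while frontier:
            nxt = []
            for v in frontier:
                for u in adj[v]:
                    if dist[u] < 0:
                        dist[u] = dist[v] + 1
                        nxt.append(u)
            frontier = nxt
        return dist

    d0 = bfs(0)
    u = int(np.argmax(d0))
    du = bfs(u)
    w = int(np.argmax(du))
    dw = bfs(w)
    return np.maximum(du, dw)


def tree_hierarchy(
    t: TreeGraph, mode: str = "default", bc: np.ndarray | None = None
) -> float:
    """Tree hierarchy Th.

    ``default``: Th = L / (2 M BC_max), bounded in (0, 1], with L the leaf
    count, M = N - 1 the edge count and BC_max the maximum normalised
    betweenness.  ``literal``: the unbounded ratio L / BC_max of leaf count
    to maximum betweenness.
    """
    if t.n_nodes < 3:
        raise UndefinedMetricError(
            "tree hierarchy is undefined for N < 3 (betweenness degenerate)"
        )
    leaves = int(np.sum(t.degrees() == 1))
    if bc is None:
        bc = betweenness(t)
    bc_max = float(np.max(bc))
    if mode == "literal":
        return leaves / bc_max
    if mode != "default":
        raise InvalidInputError(f"unknown tree-hierarchy mode {mode!r}")
    m_edges = t.n_nodes - 1
    return leaves / (2.0 * m_edges * bc_max)


def tree_metrics(t: TreeGraph, th_mode: str = "default") -> pd.DataFrame:
    """All global and nodal metrics of one tree as a tidy table.

    Columns: metric, node ('global' for tree-level metrics), value.
    """
    rows: list[tuple[str, str, float]] = []
    deg = t.degrees()
    bc = betweenness(t)
    ecc = eccentricity(t)
    rows.append(("leaf_fraction", "global", leaf_fraction(t)))
    rows.append(("degree_divergence", "global", degree_divergence(t)))
    rows.append(("tree_hierarchy", "global", tree_hierarchy(t, mode=th_mode, bc=bc)))
    for i, label in enumerate(t.labels):
        rows.append(("degree", label, float(deg[i])))
        rows.append(("betweenness", label, float(bc[i])))
        rows.append(("eccentricity", label, float(ecc[i])))
    return pd.DataFrame(rows, columns=["metric", "node", "value"])


def subject_metrics(per_epoch: list[pd.DataFrame]) -> pd.DataFrame:
    """Arithmetic mean of every metric across epochs.

    Each input is a per-epoch table from :func:`tree_metrics`; the output has
    the same (metric, node) rows with epoch-averaged values.
    """
    if not per_epoch:
        raise InvalidInputError("need at least one epoch of metrics to average")
    stacked = pd.concat(per_epoch, ignore_index=True)
    out = (
        stacked.groupby(["metric", "node"], sort=False, as_index=False)["value"]
        .mean()
    )
    counts = stacked.groupby(["metric", "node"], sort=False)["value"].size()
    if counts.nunique() != 1 or counts.iloc[0] != len(per_epoch):
        raise InvalidInputError("epoch metric tables have mismatched rows")
    return out
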