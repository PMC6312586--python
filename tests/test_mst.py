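"""Minimum spanning tree construction and topology metrics."""

import itertools

import networkx as nx
import numpy as np
import pytest

from plitree.bands import THETA
from plitree.connectivity import ConnectivityMatrix
from plitree.errors import InvalidInputError, UndefinedMetricError
from plitree.mst import (
    TreeGraph,
    betweenness,
    build_mst,
    degree_divergence,
    eccentricity,
    leaf_fraction,
    subject_metrics,
    tree_hierarchy,
    tree_metrics,
)

from conftest import prufer_to_edges, random_pli_matrix, random_tree


def exhaustive_min_tree_weight(weights: np.ndarray) -> float:
    """Minimum total weight over all labelled spanning trees (Pruefer)."""
    n = weights.shape[0]
    best = np.inf
    for prufer in itertools.product(range(n), repeat=n - 2):
        total = sum(weights[i, j] for i, j in prufer_to_edges(np.array(prufer), n))
        best = min(best, total)
    return best


class TestBuildMst:
    def test_90_node_matrix_gives_89_edges(self, rng):
        mat = random_pli_matrix(90, rng)
        tree = build_mst(mat)
        assert tree.n_nodes == 90 and len(tree.edges) == 89

    def test_three_node_example_keeps_strongest_links(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 0.9
        v[0, 2] = v[2, 0] = 0.8
        v[1, 2] = v[2, 1] = 0.1
        tree = build_mst(ConnectivityMatrix(values=v))
        edge_set = {(i, j) for i, j, _ in tree.edges}
        assert edge_set == {(0, 1), (0, 2)}

    def test_total_weight_matches_exhaustive_enumeration(self, rng):
        for _ in range(25):
            mat = random_pli_matrix(6, rng)
            w = np.where(mat.values > 0, 1.0 / np.where(mat.values > 0, mat.values, 1), 0)
            tree = build_mst(mat)
            assert tree.total_weight == pytest.approx(exhaustive_min_tree_weight(w))

    def test_agrees_with_networkx_kruskal(self, rng):
        for _ in range(10):
            mat = random_pli_matrix(12, rng)
            tree = build_mst(mat)
            g = nx.Graph()
            for i in range(12):
                for j in range(i + 1, 12):
                    g.add_edge(i, j, weight=1.0 / mat.values[i, j])
            ref = nx.minimum_spanning_tree(g, algorithm="kruskal")
            ref_w = sum(d["weight"] for _, _, d in ref.edges(data=True))
            assert tree.total_weight == pytest.approx(ref_w)

    def test_monotone_transform_leaves_edge_set_unchanged(self, rng):
        # PLI -> PLI^2 is strictly monotone, so ranks and the MST agree
        mat = random_pli_matrix(10, rng)
        sq = ConnectivityMatrix(values=mat.values**2)
        edges = lambda t: {(i, j) for i, j, _ in t.edges}
        assert edges(build_mst(mat)) == edges(build_mst(sq))

    def test_zero_pli_entries_get_sentinel_and_stay_deterministic(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 0.5
        tree1 = build_mst(ConnectivityMatrix(values=v))
        tree2 = build_mst(ConnectivityMatrix(values=v))
        assert tree1.edges == tree2.edges
        weights = sorted(w for _, _, w in tree1.edges)
        assert weights[0] == pytest.approx(2.0)
        assert weights[1] == pytest.approx(20.0)  # 10x the largest finite weight

    def test_tie_break_is_lexicographic(self):
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 0.0)
        tree = build_mst(ConnectivityMatrix(values=v))
        assert {(i, j) for i, j, _ in tree.edges} == {(0, 1), (0, 2), (0, 3)}

    def test_asymmetric_matrix_rejected(self):
        v = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(InvalidInputError):
            build_mst(ConnectivityMatrix(values=v))

    def test_starlike_limit_concentrates_degree(self, rng):
        # one node coupled to everyone much more strongly than the rest
        n = 12
        v = rng.uniform(0.01, 0.05, size=(n, n))
        v = (v + v.T) / 2
        v[0, 1:] = v[1:, 0] = 0.9
        np.fill_diagonal(v, 0.0)
        tree = build_mst(ConnectivityMatrix(values=v))
        assert tree.degrees()[0] == n - 1
        assert leaf_fraction(tree) == pytest.approx((n - 1) / n)


class TestTreeValidity:
    def test_every_mst_is_connected_acyclic_with_right_count(self, rng):
        for _ in range(10):
            tree = build_mst(random_pli_matrix(15, rng))
            g = tree.to_networkx()
            assert nx.is_tree(g)
            assert g.number_of_edges() == 14

    def test_degree_sum_is_twice_edges(self, rng):
        for n in (5, 9, 30):
            tree = random_tree(n, rng)
            assert tree.degrees().sum() == 2 * (n - 1)

    def test_wrong_edge_count_rejected(self):
        with pytest.raises(InvalidInputError):
            TreeGraph(n_nodes=4, edges=[(0, 1, 1.0), (1, 2, 1.0)])

    def test_disconnected_edge_list_rejected(self):
        with pytest.raises(InvalidInputError):
            TreeGraph(
                n_nodes=4, edges=[(0, 1, 1.0), (0, 1, 1.0), (2, 3, 1.0)]
            )


class TestGlobalMetrics:
    def test_leaf_fraction_examples(self, star4, path4):
        assert leaf_fraction(star4) == 0.75
        assert leaf_fraction(path4) == 0.5
        two = TreeGraph(n_nodes=2, edges=[(0, 1, 1.0)])
        assert leaf_fraction(two) == 1.0

    def test_degree_divergence_examples(self, star4, path4):
        # star degrees (3,1,1,1): <k^2>/<k> = 12/6; path (1,2,2,1): 10/6
        assert degree_divergence(star4) == pytest.approx(2.0)
        assert degree_divergence(path4) == pytest.approx(10 / 6)

    def test_degree_divergence_lower_bound(self, rng):
        for n in (4, 8, 16):
            tree = random_tree(n, rng)
            assert degree_divergence(tree) >= 2 * (n - 1) / n - 1e-12

    def test_tree_hierarchy_examples(self, star4, path5):
        assert tree_hierarchy(star4) == pytest.approx(0.5)  # 3 / (2*3*1)
        assert tree_hierarchy(path5) == pytest.approx(0.375)  # 2 / (2*4*(2/3))

    def test_tree_hierarchy_literal_mode(self, star4):
        assert tree_hierarchy(star4, mode="literal") == pytest.approx(3.0)

    def test_tree_hierarchy_bounded_on_random_trees(self, rng):
        for _ in range(25):
            tree = random_tree(int(rng.integers(3, 20)), rng)
            th = tree_hierarchy(tree)
            assert 0 < th <= 1

    def test_tree_hierarchy_undefined_below_three_nodes(self):
        two = TreeGraph(n_nodes=2, edges=[(0, 1, 1.0)])
        with pytest.raises(UndefinedMetricError):
            tree_hierarchy(two)


class TestNodalMetrics:
    def test_star_betweenness(self, star4):
        bc = betweenness(star4)
        assert bc[0] == 1.0
        assert np.all(bc[1:] == 0.0)

    def test_path_betweenness(self, path4):
        # node 1 is interior to pairs (0,2),(0,3) of the 3 total
        bc = betweenness(path4)
        assert bc[1] == pytest.approx(2 / 3)

    def test_betweenness_matches_path_enumeration(self, rng):
        for _ in range(15):
            tree = random_tree(7, rng)
            g = tree.to_networkx()
            n = 7
            counts = np.zeros(n)
            for a, b in itertools.combinations(range(n), 2):
                path = nx.shortest_path(g, a, b)
                for v in path[1:-1]:
                    counts[v] += 1
            oracle = counts / ((n - 1) * (n - 2) / 2)
            assert np.allclose(betweenness(tree), oracle)

    def test_leaves_have_zero_betweenness(self, rng):
        tree = random_tree(12, rng)
        bc = betweenness(tree)
        deg = tree.degrees()
        assert np.all(bc[deg == 1] == 0)

    def test_star_and_path_eccentricity(self, star4, path5):
        assert list(eccentricity(star4)) == [1, 2, 2, 2]
        ecc5 = eccentricity(path5)
        assert ecc5[0] == 4 and ecc5[-1] == 4

    def test_max_eccentricity_is_bfs_diameter(self, rng):
        for _ in range(15):
            tree = random_tree(9, rng)
            g = tree.to_networkx()
            # double-BFS diameter of a tree
            far = max(nx.single_source_shortest_path_length(g, 0).items(),
                      key=lambda kv: kv[1])[0]
            diam = max(nx.single_source_shortest_path_length(g, far).values())
            assert eccentricity(tree).max() == diam


class TestSubjectAveraging:
    def test_single_epoch_is_identity(self, star4):
        m = tree_metrics(star4)
        out = subject_metrics([m])
        assert np.allclose(out["value"].values, m["value"].values)

    def test_two_epoch_mean(self, star4, path4):
        m1, m2 = tree_metrics(star4), tree_metrics(path4)
        out = subject_metrics([m1, m2])
        deg = out.query("metric == 'degree'")["value"].values
        expected = (
            m1.query("metric == 'degree'")["value"].values
            + m2.query("metric == 'degree'")["value"].values
        ) / 2
        assert np.allclose(deg, expected)

    def test_epoch_order_invariance(self, star4, path4, path5):
        t5 = tree_metrics(path5)
        # restrict to same node count: use star4/path4 only
        a = subject_metrics([tree_metrics(star4), tree_metrics(path4)])
        b = subject_metrics([tree_metrics(path4), tree_metrics(star4)])
        assert np.allclose(a["value"].values, b["value"].values)

    def test_empty_list_rejected(self):
        with pytest.raises(InvalidInputError):
            subject_metrics([])
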