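"""Permutation testing and false-discovery-rate control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from plitree.errors import InvalidInputError
from plitree.stats import compare_groups, fdr_bh, permutation_test


class TestPermutationTest:
    def test_constant_data_gives_p_one(self):
        a = np.full(5, 3.0)
        b = np.full(7, 3.0)
        diff, p = permutation_test(a, b, n_perm=500, seed=1)
        assert diff == 0.0
        assert p == 1.0

    def test_perfect_separation_gives_minimum_p(self):
        # no permuted diff can reach the observed separation, so only the
        # add-one term counts: p = 1/(n_perm + 1)
        rng = np.random.default_rng(3)
        a = rng.normal(10.0, 0.1, size=26)
        b = rng.normal(0.0, 0.1, size=29)
        n_perm = 2000
        _, p = permutation_test(a, b, n_perm=n_perm, seed=2)
        assert p == pytest.approx(1.0 / (n_perm + 1))

    def test_exhaustive_check_on_tiny_groups(self):
        # with heavily separated tiny groups, compare against explicit
        # enumeration of all label assignments
        from itertools import combinations

        a = np.array([10.0, 11.0])
        b = np.array([0.0, 1.0, 2.0])
        pooled = np.concatenate([a, b])
        obs = a.mean() - b.mean()
        count = sum(
            abs(pooled[list(ix)].mean()
                - pooled[[i for i in range(5) if i not in ix]].mean()) >= abs(obs)
            for ix in combinations(range(5), 2)
        )
        exact_rate = count / 10  # fraction of assignments at least as extreme
        _, p = permutation_test(a, b, n_perm=4000, seed=0)
        assert p == pytest.approx((1 + 4000 * exact_rate) / 4001, abs=0.02)

    def test_label_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.3, 1.0, size=12)
        b = rng.normal(0.0, 1.0, size=15)
        d1, p1 = permutation_test(a, b, n_perm=999, seed=5)
        d2, p2 = permutation_test(b, a, n_perm=999, seed=5)
        assert d1 == pytest.approx(-d2)
        assert p1 == p2

    def test_add_one_lower_bound(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            a = rng.normal(size=4)
            b = rng.normal(size=4)
            _, p = permutation_test(a, b, n_perm=99, seed=rng)
            assert p >= 1 / 100

    def test_seed_determinism(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(size=10), rng.normal(size=12)
        r1 = permutation_test(a, b, n_perm=500, seed=42)
        r2 = permutation_test(a, b, n_perm=500, seed=42)
        assert r1 == r2

    def test_small_group_rejected(self):
        with pytest.raises(InvalidInputError):
            permutation_test(np.array([1.0]), np.arange(5.0))

    def test_null_calibration_at_multiple_levels(self):
        # under the null, P(p <= alpha) ~= alpha; binomial 99% tolerance
        n_rep = 300
        ss = np.random.SeedSequence(99)
        ps = []
        for child in ss.spawn(n_rep):
            rng = np.random.default_rng(child)
            _, p = permutation_test(
                rng.normal(size=10), rng.normal(size=12), n_perm=400, seed=rng
            )
            ps.append(p)
        ps = np.array(ps)
        for alpha in (0.05, 0.1):
            rate = np.mean(ps <= alpha)
            tol = 2.576 * np.sqrt(alpha * (1 - alpha) / n_rep)
            assert abs(rate - alpha) <= tol + 1 / 400


class TestFdrBh:
    def test_single_test_unchanged(self):
        adjusted, mask = fdr_bh(np.array([0.01]), q=0.05)
        assert adjusted[0] == pytest.approx(0.01)
        assert mask[0]

    def test_worked_ten_value_vector(self):
        # direct step-up hand computation: adjusted_(i) = min_{j>=i} m p_(j)/j
        p = np.array(
            [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216]
        )
        hand = np.array(
            [0.01, 0.04, 0.084, 0.084, 0.084, 0.1, 0.105714285714, 0.216, 0.216, 0.216]
        )
        adjusted, mask = fdr_bh(p, q=0.25)
        assert np.allclose(adjusted, hand, atol=1e-9)
        # every adjusted value is <= 0.25, so the step-up rejects all ten
        assert mask.all()
        # at q = 0.05 only the two smallest survive
        _, mask05 = fdr_bh(p, q=0.05)
        assert mask05.sum() == 2 and mask05[0] and mask05[1]

    def test_identical_p_values_unchanged(self):
        p = np.full(8, 0.03)
        adjusted, _ = fdr_bh(p)
        assert np.allclose(adjusted, 0.03)

    def test_monotone_in_raw_order(self, rng):
        p = rng.uniform(1e-4, 1.0, size=50)
        adjusted, _ = fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(adjusted[order]) >= -1e-12)
        assert np.all(adjusted >= p)

    def test_empty_vector_rejected(self):
        with pytest.raises(InvalidInputError):
            fdr_bh(np.array([]))


def _subject_tables(values: np.ndarray, nodes: list[str]) -> list[pd.DataFrame]:
    """values: (n_subjects, n_nodes) -> per-subject tidy tables."""
    out = []
    for row in values:
        out.append(
            pd.DataFrame(
                {
                    "band": "theta",
                    "metric": "degree",
                    "node": nodes,
                    "value": row,
                }
            )
        )
    return out


class TestCompareGroups:
    def test_single_node_reduces_to_permutation_test(self):
        rng = np.random.default_rng(21)
        a = rng.normal(1.0, 1.0, size=(8, 1))
        b = rng.normal(0.0, 1.0, size=(9, 1))
        out = compare_groups(
            _subject_tables(a, ["n0"]), _subject_tables(b, ["n0"]),
            n_perm=500, seed=3,
        )
        assert len(out) == 1
        row = out.iloc[0]
        assert row["p_fdr"] == row["p_raw"]  # identity FDR for m = 1
        assert row["diff"] == pytest.approx(a.mean() - b.mean())

    def test_planted_shift_detected_with_direction(self):
        rng = np.random.default_rng(22)
        nodes = [f"n{i}" for i in range(20)]
        a = rng.normal(0.0, 1.0, size=(12, 20))
        b = rng.normal(0.0, 1.0, size=(14, 20))
        a[:, 4] += 4.0
        out = compare_groups(
            _subject_tables(a, nodes), _subject_tables(b, nodes),
            n_perm=999, seed=9,
        )
        hit = out[out["node"] == "n4"].iloc[0]
        assert hit["significant"] and hit["direction"] == "+"
        others = out[(out["node"] != "n4") & out["significant"]]
        assert len(others) <= 1

    def test_null_nodal_p_values_approximately_uniform(self):
        # Kolmogorov-Smirnov on >= 200 null nodes at alpha = 0.01
        rng = np.random.default_rng(23)
        nodes = [f"n{i}" for i in range(200)]
        a = rng.normal(size=(10, 200))
        b = rng.normal(size=(11, 200))
        out = compare_groups(
            _subject_tables(a, nodes), _subject_tables(b, nodes),
            n_perm=400, seed=17,
        )
        stat = sps.kstest(out["p_raw"].values, "uniform").pvalue
        assert stat > 0.01

    def test_global_and_nodal_families_are_separate(self):
        rng = np.random.default_rng(24)

        def tables(shift):
            out = []
            for _ in range(6):
                df = pd.DataFrame(
                    {
                        "band": ["theta"] * 3 + ["theta"] * 4,
                        "metric": ["leaf_fraction", "degree_divergence",
                                   "tree_hierarchy"] + ["degree"] * 4,
                        "node": ["global"] * 3 + [f"n{i}" for i in range(4)],
                        "value": rng.normal(shift, 1.0, size=7),
                    }
                )
                out.append(df)
            return out

        out = compare_groups(tables(0.0), tables(0.2), n_perm=199, seed=5)
        assert len(out) == 7
        # global rows exist and carry their own FDR correction
        glob = out[out["node"] == "global"]
        assert set(glob["metric"]) == {
            "leaf_fraction", "degree_divergence", "tree_hierarchy"
        }
        assert (glob["p_fdr"] >= glob["p_raw"] - 1e-12).all()

    def test_mismatched_groups_rejected(self):
        rng = np.random.default_rng(25)
        a = _subject_tables(rng.normal(size=(3, 2)), ["n0", "n1"])
        b = _subject_tables(rng.normal(size=(3, 2)), ["n0", "n2"])
        with pytest.raises(InvalidInputError):
            compare_groups(a, b, n_perm=99)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(26)
        nodes = ["n0", "n1", "n2"]
        a = _subject_tables(rng.normal(size=(5, 3)), nodes)
        b = _subject_tables(rng.normal(size=(6, 3)), nodes)
        o1 = compare_groups(a, b, n_perm=500, seed=8)
        o2 = compare_groups(a, b, n_perm=500, seed=8)
        pd.testing.assert_frame_equal(o1, o2)
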