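"""Tree distances: splits, Robinson-Foulds, BHV geodesic, PCoA, region tests."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import random_binary_tree
from cortree.io import read_newick
from cortree.treedist import (
    bhv_distance,
    confidence_region_test,
    distance_group_anova,
    patristic_matrix,
    pcoa,
    pendant_lengths,
    rf_distance,
    split_lengths,
    splits,
)
from oracles import bhv_oracle


def _leafset(s):
    return frozenset(s.split())


class TestSplits:
    def test_four_leaf_binary_has_single_internal_split(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert splits(t) in ({_leafset("A B")}, {_leafset("C D")})
        assert len(splits(t)) == 1

    def test_star_tree_has_no_nontrivial_splits(self):
        assert splits(read_newick("(A:1,B:1,C:1,D:1);")) == frozenset()

    def test_caterpillar_five_leaves_two_splits(self):
        t = read_newick("((((A:1,B:1):1,C:1):1,D:1):1,E:1);")
        got = splits(t)
        assert len(got) == 2
        # normalize each expected bipartition to the side without the
        # reference leaf "A" to compare with the canonical representation
        all_tips = _leafset("A B C D E")
        expect = set()
        for side in (_leafset("A B"), _leafset("A B C")):
            expect.add(all_tips - side)
        assert got == expect

    def test_root_bifurcation_edges_merge(self):
        # rooted versions of the same unrooted tree agree on splits+lengths
        t1 = read_newick("((A:1,B:2):0.5,(C:1,D:1):0.25);")
        t2 = read_newick("(((C:1,D:1):0.75,A:1):0.0,B:2);")
        assert split_lengths(t1) == pytest.approx(split_lengths(t2))
        assert pendant_lengths(t1) == pytest.approx(pendant_lengths(t2))


class TestRobinsonFoulds:
    def test_examples(self):
        t1 = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = read_newick("((A:1,C:1):1,(B:1,D:1):1);")
        star = read_newick("(A:1,B:1,C:1,D:1);")
        assert rf_distance(t1, t1) == 0
        assert rf_distance(t1, t2) == 2
        assert rf_distance(star, t1) == 1

    def test_leafset_mismatch_raises(self):
        t1 = read_newick("((A:1,B:1):1,C:1);")
        t2 = read_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(ValueError, match="leaf sets"):
            rf_distance(t1, t2)

    def test_metric_properties_on_random_six_leaf_trees(self, rng):
        leaves = list("ABCDEF")
        trees = [random_binary_tree(rng, leaves) for _ in range(12)]
        d = np.array([[rf_distance(a, b) for b in trees] for a in trees])
        assert np.all(d == d.T)
        assert np.all(np.diag(d) == 0)
        for i in range(len(trees)):
            for j in range(len(trees)):
                if i != j and d[i, j] == 0:
                    assert splits(trees[i]) == splits(trees[j])
                for k in range(len(trees)):
                    assert d[i, k] <= d[i, j] + d[j, k]


class TestBHV:
    def test_identical_trees_distance_zero(self):
        t = read_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")
        assert bhv_distance(t, t) == pytest.approx(0.0)

    def test_same_topology_is_euclidean(self):
        t1 = read_newick("((A:1,B:1):1.0,(C:1,D:1):0.0);")
        t2 = read_newick("((A:1,B:1):3.0,(C:1,D:1):0.0);")
        assert bhv_distance(t1, t2) == pytest.approx(2.0)

    def test_incompatible_four_leaf_cone_path(self):
        # splits AB|CD (0.7) vs AC|BD (0.3) with equal pendants: cone path
        t1 = read_newick("((A:1,B:1):0.7,(C:1,D:1):0.0);")
        t2 = read_newick("((A:1,C:1):0.3,(B:1,D:1):0.0);")
        assert bhv_distance(t1, t2) == pytest.approx(1.0)

    @pytest.mark.parametrize("n_leaves", [4, 5, 6])
    def test_matches_exhaustive_support_oracle(self, n_leaves):
        rng = np.random.default_rng(1234 + n_leaves)
        leaves = [f"L{i}" for i in range(n_leaves)]
        for _ in range(40):
            t1 = random_binary_tree(rng, leaves)
            t2 = random_binary_tree(rng, leaves)
            assert bhv_distance(t1, t2) == pytest.approx(
                bhv_oracle(t1, t2), abs=1e-10
            )

    def test_bounds_on_random_tree_pairs(self, rng):
        leaves = [f"L{i}" for i in range(8)]
        for _ in range(25):
            t1 = random_binary_tree(rng, leaves)
            t2 = random_binary_tree(rng, leaves)
            d = bhv_distance(t1, t2)
            s1, s2 = split_lengths(t1), split_lengths(t2)
            p1, p2 = pendant_lengths(t1), pendant_lengths(t2)
            shared = sum((p1[l] - p2[l]) ** 2 for l in p1)
            shared += sum((s1[s] - s2.get(s, np.nan)) ** 2 for s in s1 if s in s2)
            lower = math.sqrt(shared)
            cone = math.sqrt(
                shared
                + (
                    math.sqrt(sum(s1[s] ** 2 for s in s1 if s not in s2))
                    + math.sqrt(sum(s2[s] ** 2 for s in s2 if s not in s1))
                )
                ** 2
            )
            assert lower - 1e-9 <= d <= cone + 1e-9
            if rf_distance(t1, t2) == 0:
                assert d == pytest.approx(lower)

    def test_triangle_inequality(self, rng):
        leaves = [f"L{i}" for i in range(6)]
        trees = [random_binary_tree(rng, leaves) for _ in range(8)]
        d = np.array([[bhv_distance(a, b) for b in trees] for a in trees])
        assert np.allclose(d, d.T, atol=1e-9)
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert d[i, k] <= d[i, j] + d[j, k] + 1e-9

    def test_missing_branch_length_raises(self):
        t1 = read_newick("((A,B),C);")
        t2 = read_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError):
            bhv_distance(t1, t2)


class TestPatristic:
    def test_hand_summed_three_leaf_tree(self):
        d = patristic_matrix(read_newick("((A:1,B:2):0.5,C:3);"))
        assert d.loc["A", "B"] == pytest.approx(3.0)
        assert d.loc["A", "C"] == pytest.approx(4.5)
        assert d.loc["B", "C"] == pytest.approx(5.5)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)


class TestPCoA:
    def test_collinear_points_recover_line(self):
        d = pd.DataFrame(
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]], index=list("abc"), columns=list("abc")
        )
        coords, explained = pcoa(d, k=2)
        assert explained.size == 1
        assert explained[0] == pytest.approx(1.0)
        x = coords["PCo1"].to_numpy()
        got = np.abs(x[:, None] - x[None, :])
        assert np.allclose(got, d, atol=1e-8)

    def test_equilateral_three_points(self):
        d = np.ones((3, 3)) - np.eye(3)
        _, explained = pcoa(d, k=2)
        assert explained == pytest.approx([0.5, 0.5])

    def test_zero_matrix_gives_zero_coordinates(self):
        coords, _ = pcoa(np.zeros((4, 4)), k=2)
        assert np.allclose(coords, 0)

    def test_euclidean_matrix_reproduced(self, rng):
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords, _ = pcoa(d, k=5)
        c = coords.to_numpy()
        got = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
        assert np.allclose(got, d, atol=1e-8)


class TestConfidenceRegion:
    def test_focal_equals_reference_is_inside(self, rng):
        t = random_binary_tree(rng, list("ABCDE"))
        boot = [random_binary_tree(rng, list("ABCDE")) for _ in range(10)]
        res = confidence_region_test(t, t, boot, metric="rf")
        assert res["inside"] and res["focal_distance"] == 0

    def test_far_focal_is_outside(self, rng):
        leaves = [f"L{i}" for i in range(10)]
        ref = random_binary_tree(rng, leaves)
        boot = [ref.copy() for _ in range(10)]  # all at distance 0
        focal = random_binary_tree(rng, leaves)
        if rf_distance(focal, ref) > 0:
            res = confidence_region_test(focal, ref, boot, metric="rf")
            assert not res["inside"]

    def test_quantile_rule_linear_interpolation(self):
        # distances 1..10, level 0.95 -> type-7 quantile 9.55; focal at 9 is in
        t = read_newick("((A:1,B:1):1,C:1);")
        res = confidence_region_test(t, t, [t] * 3, metric="rf", level=0.95)

        d = np.arange(1, 11, dtype=float)
        assert np.quantile(d, 0.95) == pytest.approx(9.55)

    def test_empty_forest_raises(self):
        t = read_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError):
            confidence_region_test(t, t, [])


class TestDistanceAnova:
    def test_textbook_f(self):
        res = distance_group_anova({"g1": [1, 2, 3], "g2": [2, 3, 4]})
        assert res["F"] == pytest.approx(1.5)
        assert res["df"] == (1, 4)

    def test_identical_groups(self):
        res = distance_group_anova({"a": [2, 2, 2], "b": [2, 2, 2]})
        assert res["F"] == 0.0 and res["p"] == 1.0

    def test_complete_separation(self):
        res = distance_group_anova({"a": [0, 0, 0], "b": [10, 10, 10]})
        assert res["F"] == np.inf and res["p"] == 0.0

    def test_matches_scipy_on_regular_data(self, rng):
        from scipy.stats import f_oneway

        g = {k: rng.normal(size=7).tolist() for k in "abc"}
        res = distance_group_anova(g)
        ref = f_oneway(*g.values())
        assert res["F"] == pytest.approx(ref.statistic)
        assert res["p"] == pytest.approx(ref.pvalue)

    def test_degenerate_group_raises(self):
        with pytest.raises(ValueError):
            distance_group_anova({"a": [1.0], "b": [1, 2]})
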