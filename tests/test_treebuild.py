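"""Correlation trees, bootstrap forests, leaf-shuffled random trees."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_binary_tree
from cortree.io import CountTable
from cortree.treebuild import (
    ForestConfig,
    bootstrap_forest,
    correlation_dissimilarity,
    correlation_tree,
    cluster_dissimilarity,
    random_trees,
    spearman_shared_zero,
)
from cortree.treedist import patristic_matrix, rf_distance, splits


class TestSpearmanSharedZero:
    def test_fewer_than_three_usable_positions_returns_zero(self):
        assert spearman_shared_zero([0, 0, 1, 2], [0, 0, 2, 4]) == 0.0

    def test_antitone_without_shared_zeros(self):
        assert spearman_shared_zero([0, 1, 2, 3], [5, 2, 1, 0]) == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        # usable positions leave (0,1,2,3) vs (5,0,2,4): rank covariance -1/5
        got = spearman_shared_zero([0, 0, 1, 2, 3], [0, 5, 0, 2, 4])
        assert got == pytest.approx(-0.2)

    def test_matches_scipy_when_no_zeros(self, rng):
        from scipy.stats import spearmanr

        x = rng.integers(1, 50, 30)
        y = rng.integers(1, 50, 30)
        assert spearman_shared_zero(x, y) == pytest.approx(spearmanr(x, y).statistic)

    def test_constant_restricted_vector_returns_zero(self):
        assert spearman_shared_zero([1, 1, 1, 1], [1, 2, 3, 4]) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            spearman_shared_zero([1, 2], [1, 2, 3])


class TestCorrelationDissimilarity:
    def test_identical_rows_give_zero(self):
        t = CountTable(pd.DataFrame([[1, 2, 3, 4], [2, 4, 6, 8]], index=["a", "b"]))
        d = correlation_dissimilarity(t)
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_antimonotone_rows_give_two(self):
        t = CountTable(pd.DataFrame([[1, 2, 3, 4], [9, 7, 5, 3]], index=["a", "b"]))
        assert correlation_dissimilarity(t).loc["a", "b"] == pytest.approx(2.0)

    def test_single_taxon_raises(self):
        with pytest.raises(ValueError):
            correlation_dissimilarity(CountTable(pd.DataFrame([[1, 2]], index=["a"])))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_zero_diagonal_bounded(self, seed):
        rng = np.random.default_rng(seed)
        t = CountTable(
            pd.DataFrame(
                rng.negative_binomial(1, 0.2, size=(5, 8)),
                index=[f"t{i}" for i in range(5)],
            )
        )
        d = correlation_dissimilarity(t).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 2).all()


class TestCorrelationTree:
    def test_two_taxa_cherry_splits_merge_height(self):
        # Spearman -0.2 -> dissimilarity 1.2 -> ultrametric cherry with
        # leaf branches 0.6 and patristic = cophenetic merge cost
        t = CountTable(
            pd.DataFrame([[0, 0, 1, 2, 3], [0, 5, 0, 2, 4]], index=["a", "b"])
        )
        d = correlation_dissimilarity(t)
        assert d.loc["a", "b"] == pytest.approx(1.2)
        tree = correlation_tree(t)
        assert [tip.length for tip in tree.tips()] == pytest.approx([0.6, 0.6])
        assert patristic_matrix(tree).loc["a", "b"] == pytest.approx(1.2)

    def test_identical_pair_merges_first(self):
        t = CountTable(
            pd.DataFrame(
                [[1, 2, 3, 4], [2, 4, 6, 8], [5, 1, 4, 2]], index=["x", "y", "z"]
            )
        )
        tree = correlation_tree(t)
        d = patristic_matrix(tree)
        assert d.loc["x", "y"] == pytest.approx(0.0)  # zero-cost first merge
        assert d.loc["x", "z"] > 0

    def test_leafset_and_ultrametricity(self, grouped_table):
        tree = correlation_tree(grouped_table)
        assert {t.name for t in tree.tips()} == set(grouped_table.taxa_ids)
        depths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
        vals = np.array(list(depths.values()))
        assert np.allclose(vals, vals[0], atol=1e-9)

    def test_sample_order_invariance(self, grouped_table):
        shuffled = CountTable(
            grouped_table.counts.iloc[:, ::-1], grouped_table.groups
        )
        t1 = correlation_tree(grouped_table)
        t2 = correlation_tree(shuffled)
        assert rf_distance(t1, t2) == 0
        assert np.allclose(
            patristic_matrix(t1).loc[grouped_table.taxa_ids, grouped_table.taxa_ids],
            patristic_matrix(t2).loc[grouped_table.taxa_ids, grouped_table.taxa_ids],
        )

    @pytest.mark.parametrize("variant,r_method", [("ward_d2", "ward.D2"), ("ward_d", "ward.D")])
    def test_ward_heights_match_r_hclust(self, tmp_path, rng, variant, r_method):
        """Merge heights of both Ward variants equal R's hclust output."""
        n = 8
        d = np.abs(rng.normal(1, 0.3, (n, n)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        diss = pd.DataFrame(d, index=list("abcdefgh"), columns=list("abcdefgh"))
        tree = cluster_dissimilarity(diss, ward_variant=variant)
        # node height = merge cost / 2; recover costs as 2 * root-to-node height
        root_depth = max(t.accumulate_to_ancestor(tree) for t in tree.tips())
        heights = sorted(
            2 * (root_depth - n_.accumulate_to_ancestor(tree))
            for n_ in tree.non_tips(include_self=True)
        )
        dpath = tmp_path / "d.txt"
        np.savetxt(dpath, d)
        script = (
            f'd <- as.dist(as.matrix(read.table("{dpath}")));'
            f'cat(sort(hclust(d, "{r_method}")$height), sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_heights = [float(x) for x in out.stdout.split()]
        assert heights == pytest.approx(r_heights, rel=1e-6)


class TestForests:
    def test_bootstrap_deterministic_and_sized(self, grouped_table):
        cfg = ForestConfig(n_bootstrap=5, seed=11)
        f1 = bootstrap_forest(grouped_table, cfg)
        f2 = bootstrap_forest(grouped_table, cfg)
        assert len(f1) == 5
        for a, b in zip(f1, f2):
            assert rf_distance(a, b) == 0
        for tree in f1:
            assert sum(1 for _ in tree.tips()) == grouped_table.n_taxa

    def test_constant_samples_reproduce_seed_topology(self):
        col = [3, 1, 4, 1, 5]
        df = pd.DataFrame({f"s{i}": col for i in range(8)}, index=list("abcde"))
        table = CountTable(df)
        ref = correlation_tree(table)
        for tree in bootstrap_forest(table, ForestConfig(n_bootstrap=3, seed=2)):
            assert rf_distance(tree, ref) == 0

    def test_random_trees_preserve_branch_length_multiset(self, rng):
        seed_tree = random_binary_tree(rng, [f"L{i}" for i in range(12)])
        shuffled = random_trees(seed_tree, 4, seed=5)
        ref = sorted(n.length for n in seed_tree.postorder(include_self=False))
        for tree in shuffled:
            got = sorted(n.length for n in tree.postorder(include_self=False))
            assert got == pytest.approx(ref)
            assert {t.name for t in tree.tips()} == {t.name for t in seed_tree.tips()}

    def test_random_tree_single_leaf_identity(self):
        from cortree.io import read_newick

        t = read_newick("(only:1.5);")
        out = random_trees(t, 1, seed=3)[0]
        assert [x.name for x in out.tips()] == ["only"]
        assert next(out.tips()).length == pytest.approx(1.5)

    def test_shuffled_tree_usually_moves(self, rng):
        seed_tree = random_binary_tree(rng, [f"L{i}" for i in range(20)])
        moved = [
            rf_distance(t, seed_tree) > 0 for t in random_trees(seed_tree, 10, seed=9)
        ]
        assert sum(moved) >= 9
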