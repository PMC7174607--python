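"""Correlation trees from co-abundance profiles, bootstrap and random forests.

The correlation tree clusters taxa whose abundances co-vary across samples:
pairwise Spearman correlation (excluding shared zeros), the transformation
x -> 1 - x into a dissimilarity, and Ward-linkage hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from skbio import TreeNode

from .io import CountTable

__all__ = [
    "ForestConfig",
    "spearman_shared_zero",
    "correlation_dissimilarity",
    "correlation_tree",
    "linkage_to_tree",
    "bootstrap_forest",
    "random_trees",
]

#: minimum number of usable (not both-zero) positions for a defined correlation
MIN_USABLE = 3


@dataclass
class ForestConfig:
    """Sizes of the bootstrap (N_B) and random (N_T, N_C) forests."""

    n_bootstrap: int = 100
    n_random_taxonomy: int = 100
    n_random_correlation: int = 100
    seed: int = 0

    def __post_init__(self):
        for name in ("n_bootstrap", "n_random_taxonomy", "n_random_correlation"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def spearman_shared_zero(x, y) -> float:
    """Spearman correlation excluding samples where both taxa are absent.

    Returns 0 (uninformative) when fewer than ``MIN_USABLE`` usable positions
    remain or when either restricted vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    mask = ~((x == 0) & (y == 0))
    xs, ys = x[mask], y[mask]
    if xs.size < MIN_USABLE:
        return 0.0
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return 0.0
    rx = rankdata(xs)
    ry = rankdata(ys)
    return float(np.corrcoef(rx, ry)[0, 1])


def correlation_dissimilarity(table: CountTable) -> pd.DataFrame:
    """Pairwise 1 - Spearman (shared zeros excluded); entries in [0, 2]."""
    m = table.n_taxa
    if m < 2:
        raise ValueError("need at least 2 taxa")
    arr = table.counts.to_numpy(dtype=float)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            rho = spearman_shared_zero(arr[i], arr[j])
            d[i, j] = d[j, i] = 1.0 - rho
    return pd.DataFrame(d, index=table.taxa_ids, columns=table.taxa_ids)


def correlation_tree(table: CountTable, ward_variant: str = "ward_d2") -> TreeNode:
    """Ward clustering of the correlation dissimilarity as an ultrametric tree.

    ``ward_d2`` applies the Lance-Williams recurrence to squared
    dissimilarities (R hclust ``ward.D2``, scipy's ``ward``); ``ward_d``
    applies it to the dissimilarities directly (R ``ward.D``).  Node heights
    are half the merge cost, so the patristic distance between two leaves
    equals their cophenetic merge cost.
    """
    diss = correlation_dissimilarity(table)
    return cluster_dissimilarity(diss, ward_variant=ward_variant)


def cluster_dissimilarity(diss: pd.DataFrame, ward_variant: str = "ward_d2") -> TreeNode:
    condensed = squareform(diss.to_numpy(), checks=False)
    if ward_variant == "ward_d2":
        z = linkage(condensed, method="ward")
    elif ward_variant == "ward_d":
        # scipy ward on sqrt(d) runs the ward.D recurrence on d with a final
        # square root on the heights; squaring restores the ward.D heights.
        z = linkage(np.sqrt(condensed), method="ward")
        z = z.copy()
        z[:, 2] = z[:, 2] ** 2
    else:
        raise ValueError(f"unknown ward variant {ward_variant!r}")
    return linkage_to_tree(z, list(diss.index))


def linkage_to_tree(z: np.ndarray, labels: list[str]) -> TreeNode:
    """Convert a scipy linkage matrix to an ultrametric TreeNode.

    Leaves sit at height 0, a merge node at half its merge cost, and each
    branch length is (parent height - child height).
    """
    n = len(labels)
    nodes: list[TreeNode] = [TreeNode(name=str(lab)) for lab in labels]
    heights = [0.0] * n
    for a, b, cost, _ in z:
        node = TreeNode()
        h = float(cost) / 2.0
        for idx in (int(a), int(b)):
            child = nodes[idx]
            child.length = max(h - heights[idx], 0.0)
            node.append(child)
        nodes.append(node)
        heights.append(h)
    root = nodes[-1]
    root.length = None
    return root


def bootstrap_forest(table: CountTable, cfg: ForestConfig, ward_variant: str = "ward_d2") -> list[TreeNode]:
    """Correlation trees of sample-bootstrapped tables (taxa fixed)."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples to bootstrap")
    rng = np.random.default_rng(cfg.seed)
    forest = []
    n = table.n_samples
    for _ in range(cfg.n_bootstrap):
        idx = rng.integers(0, n, size=n)
        boot = table.counts.iloc[:, idx]
        boot.columns = [f"s{i}" for i in range(n)]
        forest.append(correlation_tree(CountTable(boot), ward_variant=ward_variant))
    return forest


def random_trees(seed_tree: TreeNode, n: int, seed: int = 0) -> list[TreeNode]:
    """Copies of ``seed_tree`` with leaf labels permuted uniformly at random.

    Topology and the multiset of branch lengths are preserved exactly.
    """
    rng = np.random.default_rng(seed)
    labels = [t.name for t in seed_tree.tips()]
    out = []
    for _ in range(n):
        perm = rng.permutation(len(labels))
        tree = seed_tree.copy()
        for tip, k in zip(tree.tips(), perm):
            tip.name = labels[k]
        out.append(tree)
    return out
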