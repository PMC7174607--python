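"""Top-down hierarchical FDR over a hypothesis tree.

Every node of the tree carries a hypothesis: leaves test single taxa,
internal nodes test the per-sample sum of their descendant taxa's
(normalized) abundances.  Testing starts at the root's children and only
descends below rejected nodes; each family of children is corrected with a
Benjamini-Hochberg procedure at the within-family level alpha.  The
procedure guarantees an a-posteriori leaf-level FDR of

    alpha' = 1.44 * alpha * (#leaf discoveries + #families tested)
                           / (#leaf discoveries + 1).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import datest
from .io import CountTable

__all__ = ["HFDRResult", "aggregate_node", "hfdr_run", "hfdr_traverse", "posterior_fdr"]

UNIVERSAL_FACTOR = 1.44


@dataclass
class HFDRResult:
    nodes: pd.DataFrame  # index node id; columns: is_leaf, p, p_adj, tested, rejected
    discoveries_all: set[str]
    discoveries_leaves: set[str]
    families_tested: int
    alpha: float
    alpha_prime: float


def posterior_fdr(alpha: float, n_leaf_discoveries: int, n_families: int) -> float:
    """A-posteriori leaf-level FDR bound, with the universal 1.44 factor."""
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if n_leaf_discoveries < 0:
        raise ValueError("n_leaf_discoveries must be >= 0")
    return (
        UNIVERSAL_FACTOR
        * alpha
        * (n_leaf_discoveries + n_families)
        / (n_leaf_discoveries + 1)
    )


def _name_nodes(tree: TreeNode) -> TreeNode:
    """Copy of the tree with unique names on every node."""
    tree = tree.copy()
    seen = set()
    counter = 0
    for node in tree.postorder():
        if node.name is None or node.name in seen:
            while f"node{counter}" in seen:
                counter += 1
            node.name = f"node{counter}"
        seen.add(node.name)
    return tree


def aggregate_node(values: pd.DataFrame, node: TreeNode) -> np.ndarray:
    """Per-sample sum of the (normalized) abundances below ``node``."""
    leaves = [t.name for t in node.tips()] or [node.name]
    missing = [l for l in leaves if l not in values.index]
    if missing:
        raise ValueError(f"leaves without matching taxa: {missing}")
    return values.loc[leaves].to_numpy().sum(axis=0)


def hfdr_traverse(
    children: dict[str, list[str]],
    leaves: set[str],
    pvalues: dict[str, float],
    alpha: float,
    root: str,
) -> tuple[set[str], int, dict[str, float]]:
    """Algorithm: BH within each family of children, descending below
    rejections only.  Returns (discoveries, families tested, adjusted p)."""
    discoveries: set[str] = set()
    p_adj: dict[str, float] = {}
    families = 0
    queue = deque([root])
    while queue:
        node = queue.popleft()
        fam = children.get(node, [])
        if not fam:
            continue
        p = np.array([pvalues[c] for c in fam])
        adj, rej = datest.bh_adjust(p, alpha)
        families += 1
        for child, a, r in zip(fam, adj, rej):
            p_adj[child] = float(a)
            if r:
                discoveries.add(child)
                if child not in leaves:
                    queue.append(child)
    return discoveries, families, p_adj


def hfdr_run(
    table: CountTable,
    tree: TreeNode,
    alpha: float = 0.05,
    test: str = "anova_f",
    normalization: str = "tss",
) -> HFDRResult:
    """Hierarchical FDR on a hypothesis tree whose leaves are the taxa.

    ``normalization="none"`` reproduces testing on raw counts.  The root
    carries no hypothesis; the first family tested is the root's children.
    """
    if table.groups is None:
        raise ValueError("group labels required")
    tree = _name_nodes(tree)
    tip_names = {t.name for t in tree.tips()}
    if tip_names != set(table.taxa_ids):
        raise ValueError(
            f"tree/taxa mismatch: only in tree {sorted(tip_names - set(table.taxa_ids))[:5]}, "
            f"only in table {sorted(set(table.taxa_ids) - tip_names)[:5]}"
        )
    values = datest.normalize(table, normalization)

    children: dict[str, list[str]] = {}
    pvalues: dict[str, float] = {}
    is_leaf: dict[str, bool] = {}
    for node in tree.postorder():
        is_leaf[node.name] = node.is_tip()
        if not node.is_tip():
            children[node.name] = [c.name for c in node.children]
        if node is not tree:
            agg = aggregate_node(values, node)
            pvalues[node.name] = float(
                datest.group_test_pvalues(agg[None, :], table.groups, test)[0]
            )

    discoveries, families, p_adj = hfdr_traverse(
        children, {n for n, l in is_leaf.items() if l}, pvalues, alpha, tree.name
    )
    leaf_disc = {d for d in discoveries if is_leaf[d]}
    ids = [n.name for n in tree.postorder() if n is not tree]
    nodes = pd.DataFrame(
        {
            "is_leaf": [is_leaf[i] for i in ids],
            "p": [pvalues[i] for i in ids],
            "p_adj": [p_adj.get(i, np.nan) for i in ids],
            "tested": [i in p_adj for i in ids],
            "rejected": [i in discoveries for i in ids],
        },
        index=ids,
    )
    return HFDRResult(
        nodes=nodes,
        discoveries_all=discoveries,
        discoveries_leaves=leaf_disc,
        families_tested=families,
        alpha=alpha,
        alpha_prime=posterior_fdr(alpha, len(leaf_disc), max(families, 1)),
    )
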