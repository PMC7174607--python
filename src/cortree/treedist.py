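"""Distances and statistics on trees: Robinson-Foulds, BHV geodesic, PCoA.

Trees are compared as unrooted weighted trees.  The Robinson-Foulds distance
is the symmetric difference of the internal split sets (branch lengths
ignored); the Billera-Holmes-Vogtmann distance is the exact geodesic length
in treespace, computed with the geodesic-tree-path (GTP) algorithm of Owen
and Provan: incompatible splits are partitioned into an ordered sequence of
support pairs by iteratively solving minimum-weight vertex covers of the
split-incompatibility bipartite graph (via max-flow min-cut).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

__all__ = [
    "splits",
    "split_lengths",
    "pendant_lengths",
    "splits_compatible",
    "rf_distance",
    "bhv_distance",
    "patristic_matrix",
    "pcoa",
    "confidence_region_test",
    "distance_group_anova",
    "TreeDistanceReport",
]

COVER_TOL = 1e-12


@dataclass
class TreeDistanceReport:
    label_1: str
    label_2: str
    rf: int
    bhv: float


# ---------------------------------------------------------------------------
# splits


def _edge_clades(tree: TreeNode):
    """(clade tip-set, length) per edge of the unrooted view of ``tree``.

    A bifurcating root contributes a single merged edge whose length is the
    sum of the two root-child branch lengths.
    """
    children = tree.children
    merged = len(children) == 2
    edges = []
    for node in tree.postorder(include_self=False):
        clade = frozenset(t.name for t in node.tips()) or frozenset([node.name])
        length = node.length if node.length is not None else 0.0
        if merged and node.parent is tree and node is children[1]:
            continue  # second root edge merges with the first
        if merged and node.parent is tree and node is children[0]:
            other = children[1]
            length = length + (other.length or 0.0)
        edges.append((clade, float(length)))
    return edges


def _normalize(clade: frozenset, all_tips: frozenset, ref) -> frozenset:
    """Canonical side of a bipartition: the side not containing ``ref``."""
    return frozenset(all_tips - clade) if ref in clade else clade


def split_lengths(tree: TreeNode) -> dict[frozenset, float]:
    """Non-trivial bipartitions of the unrooted tree, with branch lengths."""
    tips = frozenset(t.name for t in tree.tips())
    ref = min(tips)
    n = len(tips)
    out: dict[frozenset, float] = {}
    for clade, length in _edge_clades(tree):
        if len(clade) < 2 or len(clade) > n - 2:
            continue
        key = _normalize(clade, tips, ref)
        out[key] = out.get(key, 0.0) + length
    return out


def splits(tree: TreeNode) -> frozenset:
    """The set of non-trivial splits (topology only)."""
    return frozenset(split_lengths(tree))


def pendant_lengths(tree: TreeNode) -> dict[str, float]:
    """Leaf-edge length per tip of the unrooted view."""
    tips = frozenset(t.name for t in tree.tips())
    n = len(tips)
    out: dict[str, float] = {}
    for clade, length in _edge_clades(tree):
        side = clade if len(clade) <= n - len(clade) else tips - clade
        if len(side) == 1:
            (name,) = side
            out[name] = out.get(name, 0.0) + length
    return out


def splits_compatible(a: frozenset, b: frozenset, all_tips: frozenset) -> bool:
    """Two bipartitions can coexist in one tree iff some quadrant is empty."""
    return (
        not (a & b)
        or a <= b
        or b <= a
        or (a | b) == all_tips
    )


def _check_same_leaves(t1: TreeNode, t2: TreeNode) -> frozenset:
    l1 = frozenset(t.name for t in t1.tips())
    l2 = frozenset(t.name for t in t2.tips())
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, "
            f"only in second {sorted(l2 - l1)}"
        )
    return l1


# ---------------------------------------------------------------------------
# Robinson-Foulds


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Symmetric difference of split sets = minimal contraction/expansion count."""
    _check_same_leaves(t1, t2)
    return len(splits(t1) ^ splits(t2))


# ---------------------------------------------------------------------------
# BHV geodesic (GTP)


def _norm(lengths: dict[frozenset, float], subset) -> float:
    return math.sqrt(sum(lengths[s] ** 2 for s in subset))


# capacities are scaled to integers for scipy's max-flow, which works in
# int32; the cover weight is recomputed exactly in floats afterwards
_FLOW_SCALE = 10**8
_FLOW_BIG = 10**9


def _min_vertex_cover(a_splits, b_splits, wa, wb, edges):
    """Min-weight vertex cover of the bipartite incompatibility graph.

    Solved as a min s-t cut (max-flow) with source->A capacities ``wa``,
    B->sink capacities ``wb`` and effectively infinite incompatibility
    edges; weights are scaled to integers for scipy's max-flow and the
    cover weight is recomputed exactly from the cut partition.  Returns
    (cover weight, cover_A, cover_B).
    """
    from scipy.sparse import csr_array
    from scipy.sparse.csgraph import maximum_flow

    na, nb = len(a_splits), len(b_splits)
    n = na + nb + 2
    src, snk = 0, n - 1
    big = _FLOW_BIG
    rows, cols, caps = [], [], []
    for i in range(na):
        rows.append(src)
        cols.append(1 + i)
        caps.append(max(int(round(wa[i] * _FLOW_SCALE)), 0))
    for j in range(nb):
        rows.append(1 + na + j)
        cols.append(snk)
        caps.append(max(int(round(wb[j] * _FLOW_SCALE)), 0))
    for i, j in edges:
        rows.append(1 + i)
        cols.append(1 + na + j)
        caps.append(big)
    graph = csr_array((caps, (rows, cols)), shape=(n, n), dtype=np.int64)
    flow = maximum_flow(graph, src, snk).flow
    residual = graph - flow
    # BFS on the residual graph (flow matrix already contains the reverse
    # residual arcs as negative entries, so residual > 0 covers both)
    reach = np.zeros(n, dtype=bool)
    reach[src] = True
    stack = [src]
    res = residual.tolil()
    while stack:
        u = stack.pop()
        row = res.rows[u]
        data = res.data[u]
        for v, c in zip(row, data):
            if c > 0 and not reach[v]:
                reach[v] = True
                stack.append(v)
    cover_a = {a_splits[i] for i in range(na) if not reach[1 + i]}
    cover_b = {b_splits[j] for j in range(nb) if reach[1 + na + j]}
    weight = sum(wa[i] for i in range(na) if not reach[1 + i]) + sum(
        wb[j] for j in range(nb) if reach[1 + na + j]
    )
    return weight, cover_a, cover_b


def _incompatibility_edges(a_list, b_list, all_tips):
    return [
        (i, j)
        for i, a in enumerate(a_list)
        for j, b in enumerate(b_list)
        if not splits_compatible(a, b, all_tips)
    ]


def _gtp_support(A, B, la, lb, all_tips):
    """Refine the single pair (A, B) into the geodesic support sequence.

    Each pair failing the min-cover >= 1 condition is split using the
    minimising cover (C_A, C_B) into (C_A, B \\ C_B), (A \\ C_A, C_B).  Pairs
    with an empty side are independent coordinates and are never split.
    """
    pairs = [(set(A), set(B))]
    done: list[tuple[set, set]] = []
    while pairs:
        ai, bi = pairs.pop(0)
        if not ai or not bi:
            done.append((ai, bi))
            continue
        skey = lambda s: tuple(sorted(s))
        a_list, b_list = sorted(ai, key=skey), sorted(bi, key=skey)
        edges = _incompatibility_edges(a_list, b_list, all_tips)
        if not edges:
            done.append((ai, set()))
            done.append((set(), bi))
            continue
        na2 = sum(la[s] ** 2 for s in ai)
        nb2 = sum(lb[s] ** 2 for s in bi)
        wa = [la[s] ** 2 / na2 for s in a_list]
        wb = [lb[s] ** 2 / nb2 for s in b_list]
        weight, ca, cb = _min_vertex_cover(a_list, b_list, wa, wb, edges)
        if weight < 1.0 - COVER_TOL and (ca != ai or cb != bi):
            pairs.insert(0, (set(ai) - ca, set(cb)))
            pairs.insert(0, (set(ca), set(bi) - cb))
        else:
            done.append((ai, bi))
    return done


def bhv_distance(t1: TreeNode, t2: TreeNode) -> float:
    """Exact Billera-Holmes-Vogtmann geodesic distance between two trees.

    Pendant edges and shared splits contribute squared length differences;
    each support pair (A_i, B_i) of incompatible splits contributes
    (||A_i|| + ||B_i||)^2.  Reduces to the Euclidean distance when the
    topologies agree and is bounded above by the cone path through the star
    tree.
    """
    all_tips = _check_same_leaves(t1, t2)
    for t in (t1, t2):
        for node in t.postorder(include_self=False):
            if node.length is None:
                raise ValueError(f"missing branch length at node {node.name!r}")
    s1, s2 = split_lengths(t1), split_lengths(t2)
    p1, p2 = pendant_lengths(t1), pendant_lengths(t2)
    for name in all_tips:
        if name not in p1 or name not in p2:
            raise ValueError(f"missing branch length for leaf {name!r}")

    total = sum((p1[n] - p2[n]) ** 2 for n in all_tips)
    common = set(s1) & set(s2)
    total += sum((s1[s] - s2[s]) ** 2 for s in common)

    A = {s for s in s1 if s not in common}
    B = {s for s in s2 if s not in common}
    if A or B:
        for ai, bi in _gtp_support(A, B, s1, s2, all_tips):
            total += (_norm(s1, ai) + _norm(s2, bi)) ** 2
    return math.sqrt(total)


# ---------------------------------------------------------------------------
# patristic matrix, PCoA


def patristic_matrix(tree: TreeNode) -> pd.DataFrame:
    """Leaf-to-leaf path lengths (sums of branch lengths)."""
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def pcoa(dist, k: int = 2):
    """Classical metric MDS of a distance matrix.

    Double-centres ``-d^2/2``, eigendecomposes, keeps positive eigenvalues
    and returns up to ``k`` coordinate axes (ordered by eigenvalue, defined
    up to sign) plus the explained-variance fractions of all positive axes.
    """
    labels = list(dist.index) if isinstance(dist, pd.DataFrame) else None
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12 if evals.max() > 0 else evals > 0
    n_pos = int(pos.sum())
    k_eff = min(k, n_pos)
    coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff]) if k_eff else np.zeros((n, 0))
    explained = evals[:n_pos] / evals[:n_pos].sum() if n_pos else np.zeros(0)
    if n_pos == 0:
        coords = np.zeros((n, k))
        k_eff = k
    coords = pd.DataFrame(
        coords, index=labels, columns=[f"PCo{i+1}" for i in range(coords.shape[1])]
    )
    return coords, explained


# ---------------------------------------------------------------------------
# confidence region and ANOVA


def confidence_region_test(
    focal: TreeNode,
    reference: TreeNode,
    boot: list[TreeNode],
    metric: str = "bhv",
    level: float = 0.95,
) -> dict:
    """Is ``focal`` within the bootstrap confidence region of ``reference``?

    Membership: d(focal, reference) <= empirical ``level``-quantile (linear
    interpolation between order statistics, numpy's default) of the
    bootstrap-to-reference distances.
    """
    if not boot:
        raise ValueError("bootstrap forest is empty")
    dist = {"rf": rf_distance, "bhv": bhv_distance}[metric]
    focal_d = dist(focal, reference)
    boot_d = np.array([dist(b, reference) for b in boot], dtype=float)
    q = float(np.quantile(boot_d, level))
    return {
        "inside": bool(focal_d <= q),
        "focal_distance": float(focal_d),
        "quantile": q,
        "level": level,
        "boot_distances": boot_d,
    }


def distance_group_anova(groups: dict[str, list], tukey: bool = False) -> dict:
    """One-way ANOVA of distance-to-reference values across tree groups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
    values = np.concatenate(list(arrays.values()))
    grand = values.mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in arrays.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    df1 = len(arrays) - 1
    df2 = values.size - len(arrays)
    msw = ssw / df2
    if msw <= np.finfo(float).tiny:
        if ssb <= np.finfo(float).tiny:
            f, p = 0.0, 1.0
        else:
            f, p = np.inf, 0.0  # complete separation; p underflows
    else:
        f = (ssb / df1) / msw
        p = float(stats.f.sf(f, df1, df2))
    out = {"F": float(f), "p": p, "df": (df1, df2)}
    if tukey:
        res = stats.tukey_hsd(*arrays.values())
        out["tukey"] = {"labels": list(arrays), "pvalues": res.pvalue}
    return out
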