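"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths: the BHV oracle
enumerates every valid support sequence instead of running the
vertex-cover refinement, and the BH oracle applies the step-up definition
literally.
"""

import itertools
import math

import numpy as np

from cortree.treedist import (
    pendant_lengths,
    split_lengths,
    splits_compatible,
)


def _ordered_partitions(items, k):
    """All ways to place ``items`` into k ordered non-empty blocks."""
    items = list(items)
    if k == 1:
        yield [set(items)]
        return
    for assignment in itertools.product(range(k), repeat=len(items)):
        if set(assignment) != set(range(k)):
            continue
        blocks = [set() for _ in range(k)]
        for it, a in zip(items, assignment):
            blocks[a].add(it)
        yield blocks


def bhv_oracle(t1, t2):
    """Geodesic length by exhaustive enumeration of support sequences.

    A support ((A_1,B_1),...,(A_k,B_k)) is admissible when A_j is compatible
    with B_i for every i < j (the intermediate orthants exist) and the norm
    ratios ||A_i||/||B_i|| are non-decreasing (the multi-segment straight
    path is realizable); its length is
    sqrt(sum_common (dl)^2 + sum_i (||A_i|| + ||B_i||)^2).
    """
    tips = frozenset(t.name for t in t1.tips())
    s1, s2 = split_lengths(t1), split_lengths(t2)
    p1, p2 = pendant_lengths(t1), pendant_lengths(t2)
    base = sum((p1[n] - p2[n]) ** 2 for n in tips)
    common = set(s1) & set(s2)
    base += sum((s1[s] - s2[s]) ** 2 for s in common)
    A = {s for s in s1 if s not in common}
    B = {s for s in s2 if s not in common}
    # splits compatible with the entire other tree shrink/grow independently
    solo_a = {a for a in A if all(splits_compatible(a, b, tips) for b in B)}
    solo_b = {b for b in B if all(splits_compatible(a, b, tips) for a in A)}
    base += sum(s1[a] ** 2 for a in solo_a) + sum(s2[b] ** 2 for b in solo_b)
    A, B = A - solo_a, B - solo_b
    if not A and not B:
        return math.sqrt(base)
    assert A and B

    def norm(lengths, subset):
        return math.sqrt(sum(lengths[s] ** 2 for s in subset))

    best = np.inf
    for k in range(1, min(len(A), len(B)) + 1):
        for ablocks in _ordered_partitions(A, k):
            for bblocks in _ordered_partitions(B, k):
                ok = all(
                    splits_compatible(a, b, tips)
                    for i in range(k)
                    for j in range(i + 1, k)
                    for a in ablocks[j]
                    for b in bblocks[i]
                )
                if not ok:
                    continue
                ratios = [
                    norm(s1, ablocks[i]) / norm(s2, bblocks[i]) for i in range(k)
                ]
                if any(r2 < r1 - 1e-12 for r1, r2 in zip(ratios, ratios[1:])):
                    continue
                length = base + sum(
                    (norm(s1, ablocks[i]) + norm(s2, bblocks[i])) ** 2
                    for i in range(k)
                )
                best = min(best, length)
    return math.sqrt(best)


def bh_stepup_oracle(p, alpha):
    """Literal Benjamini-Hochberg step-up: reject p_(1..k*) for the largest
    k* with p_(k*) <= k* alpha / m; adjusted p by the monotone cap."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = alpha * np.arange(1, m + 1) / m
    below = np.nonzero(sorted_p <= thresh)[0]
    k_star = below.max() + 1 if below.size else 0
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_star]] = True
    adj = np.minimum.accumulate((sorted_p * m / np.arange(1, m + 1))[::-1])[::-1]
    p_adj = np.empty(m)
    p_adj[order] = np.minimum(adj, 1.0)
    return p_adj, rejected
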