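"""Per-taxon differential-abundance testing.

Normalization (TSS or TMM), rank tests (Wilcoxon rank-sum, Kruskal-Wallis)
and the one-way ANOVA F-test, the p -> z transform z = Phi^{-1}(p) (lower
tail carries the evidence), and the Benjamini-Hochberg baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountTable

__all__ = [
    "TestResult",
    "normalize",
    "tmm_factors",
    "taxon_test",
    "p_to_z",
    "bh_adjust",
]

P_CLAMP = 1e-15


@dataclass
class TestResult:
    """Per-taxon p-values, z-scores, evidences and BH-adjusted decisions."""

    table: pd.DataFrame  # columns: p, z, evidence, p_adj, rejected
    method: str
    alpha: float

    @property
    def taxa_ids(self):
        return list(self.table.index)

    @property
    def p(self) -> pd.Series:
        return self.table["p"]

    @property
    def z(self) -> pd.Series:
        return self.table["z"]

    @property
    def rejected(self) -> pd.Series:
        return self.table["rejected"]

    def discoveries(self) -> set[str]:
        return set(self.table.index[self.table["rejected"]])


# ---------------------------------------------------------------------------
# normalization


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors (edgeR recipe).

    Reference sample: upper quartile of nonzero-scaled counts closest to the
    mean upper quartile.  Per sample, M (log2 ratio to the reference) and A
    (average log2 abundance) are computed over taxa positive in both, the
    30% most extreme M and 5% most extreme A are trimmed on each side, and
    the factor is the precision-weighted mean M.  Factors are normalized to
    geometric mean 1.
    """
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if np.any(lib == 0):
        bad = counts.columns[lib == 0].tolist()
        raise ValueError(f"all-zero samples: {bad}")
    scaled = y / lib
    f75 = np.array([np.quantile(scaled[y[:, i] > 0, i], 0.75) for i in range(y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(y.shape[1])
    yr, nr = y[:, ref], lib[ref]
    for i in range(y.shape[1]):
        if i == ref:
            continue
        yi, ni = y[:, i], lib[i]
        fin = (yi > 0) & (yr > 0)
        if fin.sum() == 0:
            continue
        pi, pr = yi[fin] / ni, yr[fin] / nr
        m = np.log2(pi / pr)
        a = 0.5 * np.log2(pi * pr)
        w = (ni - yi[fin]) / (ni * yi[fin]) + (nr - yr[fin]) / (nr * yr[fin])
        if np.max(np.abs(m)) < 1e-10:
            continue
        n = fin.sum()
        lo_l = np.floor(n * 0.3) + 1
        hi_l = n + 1 - lo_l
        lo_s = np.floor(n * 0.05) + 1
        hi_s = n + 1 - lo_s
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
        if keep.sum() == 0 or w[keep].sum() == 0:
            continue
        f = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
        factors[i] = f if np.isfinite(f) and f > 0 else 1.0
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm")


def normalize(table: CountTable, method: str = "tmm") -> pd.DataFrame:
    """Normalized abundances: TSS relative abundances or TMM-scaled counts."""
    counts = table.counts
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = lib.index[lib == 0].tolist()
        raise ValueError(f"all-zero samples: {bad}")
    if method == "tss":
        return counts / lib
    if method == "tmm":
        return counts / (lib * tmm_factors(counts))
    if method in ("none", None):
        return counts.astype(float)
    raise ValueError(f"unknown normalization {method!r}")


# ---------------------------------------------------------------------------
# tests


def _group_arrays(values: np.ndarray, groups: pd.Series):
    labels = pd.unique(groups)
    return [values[:, (groups == lab).to_numpy()] for lab in labels]


def group_test_pvalues(values: np.ndarray, groups: pd.Series, test: str) -> np.ndarray:
    """Row-wise p-values for a 2D array (features x samples).

    Wilcoxon uses the exact two-sided null when both groups have <= 10
    samples and the row has no ties, otherwise the normal approximation with
    tie correction.  Constant rows get p = 1.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    parts = _group_arrays(values, groups)
    for part in parts:
        if part.shape[1] < 2:
            raise ValueError("every group needs at least 2 samples")
    if test == "wilcoxon":
        if len(parts) != 2:
            raise ValueError("wilcoxon requires exactly 2 groups")
        a, b = parts
        p = stats.mannwhitneyu(a, b, axis=1, method="asymptotic").pvalue
        if a.shape[1] <= 10 and b.shape[1] <= 10:
            for i in range(values.shape[0]):
                row = values[i]
                if np.unique(row).size == row.size:  # no ties anywhere
                    p[i] = stats.mannwhitneyu(a[i], b[i], method="exact").pvalue
    elif test == "kruskal":
        p = stats.kruskal(*parts, axis=1).pvalue
    elif test == "anova_f":
        p = stats.f_oneway(*parts, axis=1).pvalue
    else:
        raise ValueError(f"unknown test {test!r}")
    p = np.asarray(p, dtype=float)
    constant = np.all(values == values[:, :1], axis=1)
    p[constant | ~np.isfinite(p)] = 1.0
    return np.clip(p, 0.0, 1.0)


def taxon_test(
    table: CountTable,
    test: str = "wilcoxon",
    normalization: str = "tmm",
    alpha: float = 0.05,
    groups: pd.Series | None = None,
) -> TestResult:
    """Per-taxon test of the named kind on normalized abundances."""
    groups = table.groups if groups is None else groups.reindex(table.sample_ids)
    if groups is None:
        raise ValueError("no group labels available")
    values = normalize(table, normalization).to_numpy()
    p = group_test_pvalues(values, groups, test)
    z = p_to_z(p)
    p_adj, rejected = bh_adjust(p, alpha)
    df = pd.DataFrame(
        {
            "p": p,
            "z": z,
            "evidence": -np.log10(np.clip(p, P_CLAMP, None)),
            "p_adj": p_adj,
            "rejected": rejected,
        },
        index=table.taxa_ids,
    )
    return TestResult(df, method=f"{test}+{normalization}", alpha=alpha)


def p_to_z(p) -> np.ndarray:
    """z = Phi^{-1}(p) with p clamped to [1e-15, 1 - 1e-15]; small p -> very
    negative z, so all downstream rejection regions are lower-tail."""
    p = np.asarray(p, dtype=float)
    return stats.norm.ppf(np.clip(p, P_CLAMP, 1 - P_CLAMP))


def bh_adjust(p, alpha: float = 0.05):
    """Benjamini-Hochberg step-up: adjusted p-values and rejections."""
    p = np.asarray(p, dtype=float)
    rejected, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, rejected
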