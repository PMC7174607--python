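"""Synthetic benchmark data for differential-abundance procedures.

Two schemes mirror common practice for gut-microbiome benchmarks:

* parametric — a Dirichlet-multinomial model is fitted to (or supplied for)
  a seed table; each sample draws a proportion vector from the Dirichlet, a
  sequencing depth from NB(mean 10,000, size 25) and counts from the
  multinomial;
* non-parametric — a real (or stand-in) count table is used verbatim.

In both, samples are split into two balanced groups and the counts of a
known set of differential taxa are multiplied by a fold change in group B,
so that true-positive rates and false discovery rates are computable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountTable

__all__ = [
    "DirichletMultinomialParams",
    "DepthModel",
    "SimulationDesign",
    "SimulationTruth",
    "fit_dm",
    "generate_parametric",
    "generate_nonparametric",
    "synthetic_seed_table",
]

PREVALENT = 0.9  # prevalence floor of the `prevalent_90` differential pool


@dataclass
class DirichletMultinomialParams:
    """Dirichlet concentration per taxon (called dm_alpha to avoid clashing
    with the smoothing prior mean)."""

    dm_alpha: pd.Series

    def __post_init__(self):
        self.dm_alpha = pd.Series(self.dm_alpha, dtype=float)
        if (self.dm_alpha <= 0).any():
            raise ValueError("concentration parameters must be > 0")

    @property
    def precision(self) -> float:
        return float(self.dm_alpha.sum())


@dataclass
class DepthModel:
    """Negative-binomial sequencing depth: variance = mean + mean^2/size."""

    mean: float = 10_000.0
    size: float = 25.0

    def __post_init__(self):
        if self.mean <= 0 or self.size <= 0:
            raise ValueError("mean and size must be > 0")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.size / (self.size + self.mean)
        return rng.negative_binomial(self.size, p, size=n)


@dataclass
class SimulationDesign:
    n_samples: int = 100
    n_taxa: int = 100
    n_diff: int = 10
    fold_change: float = 5.0
    diff_pool: str = "all_taxa"  # or "prevalent_90"
    scheme: str = "parametric"
    seed: int = 0
    allow_large_n_diff: bool = False

    def __post_init__(self):
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if self.diff_pool not in ("all_taxa", "prevalent_90"):
            raise ValueError(f"unknown diff pool {self.diff_pool!r}")
        if self.n_diff > 0.2 * self.n_taxa and not self.allow_large_n_diff:
            raise ValueError(
                "n_diff exceeds 20% of taxa; set allow_large_n_diff to override"
            )


@dataclass
class SimulationTruth:
    groups: pd.Series
    diff_taxa: set[str]
    fold_change: float


def fit_dm(table: CountTable) -> DirichletMultinomialParams:
    """Method-of-moments Dirichlet-multinomial fit on per-sample proportions.

    The mean proportions give the concentration profile; the precision comes
    from the average overdispersion theta of the proportion variances,
    theta = var / (m (1 - m)), with precision A = (1 - theta) / theta.
    """
    if table.n_samples < 5:
        raise ValueError("need at least 5 samples")
    if (table.counts.sum(axis=1) == 0).any():
        raise ValueError("remove all-zero taxa before fitting")
    props = table.counts / table.counts.sum(axis=0)
    m = props.mean(axis=1)
    v = props.var(axis=1, ddof=1)
    denom = m * (1 - m)
    usable = denom > 0
    theta = float((v[usable] / denom[usable]).mean())
    if theta <= 1e-12:
        raise ValueError(
            "no overdispersion (all samples identical?); add a pseudocount"
        )
    if theta >= 1:
        theta = 1 - 1e-6
    precision = (1 - theta) / theta
    return DirichletMultinomialParams(m * precision)


def _balanced_groups(rng: np.random.Generator, sample_ids) -> pd.Series:
    n = len(sample_ids)
    labels = np.array(["A"] * ((n + 1) // 2) + ["B"] * (n // 2))
    return pd.Series(labels[rng.permutation(n)], index=sample_ids)


def _inject_fold_change(
    counts: pd.DataFrame,
    groups: pd.Series,
    rng: np.random.Generator,
    n_diff: int,
    fold: float,
    pool: pd.Index,
) -> tuple[pd.DataFrame, set[str]]:
    if n_diff > len(pool):
        raise ValueError(
            f"n_diff={n_diff} exceeds the differential pool size {len(pool)}"
        )
    diff = set(rng.choice(pool.to_numpy(), size=n_diff, replace=False))
    out = counts.copy()
    b_cols = groups.index[groups == "B"]
    block = out.loc[sorted(diff), b_cols] * fold
    # integer folds stay exact; non-integer folds round half-to-even
    out.loc[sorted(diff), b_cols] = np.rint(block).astype(np.int64)
    return out, diff


def generate_parametric(
    params: DirichletMultinomialParams,
    depth: DepthModel,
    design: SimulationDesign,
) -> tuple[CountTable, SimulationTruth]:
    """Dirichlet-multinomial tables with fold-change injection in group B."""
    rng = np.random.default_rng(design.seed)
    alpha = params.dm_alpha.to_numpy()
    taxa = list(params.dm_alpha.index)
    n = design.n_samples
    depths = depth.draw(rng, n)
    counts = np.empty((len(taxa), n), dtype=np.int64)
    for i in range(n):
        p = rng.dirichlet(alpha)
        counts[:, i] = rng.multinomial(depths[i], p)
    df = pd.DataFrame(counts, index=taxa, columns=[f"s{i}" for i in range(n)])
    groups = _balanced_groups(rng, df.columns)
    base = CountTable(df)
    if design.diff_pool == "prevalent_90":
        pool = base.counts.index[base.prevalence() >= PREVALENT]
    else:
        pool = base.counts.index
    injected, diff = _inject_fold_change(
        df, groups, rng, design.n_diff, design.fold_change, pool
    )
    table = CountTable(injected, groups)
    return table, SimulationTruth(groups, diff, design.fold_change)


def generate_nonparametric(
    seed_table: CountTable,
    design: SimulationDesign,
) -> tuple[CountTable, SimulationTruth]:
    """Seed table kept verbatim; differential taxa drawn from the highly
    prevalent pool (prevalence >= 0.9) unless the design says otherwise."""
    rng = np.random.default_rng(design.seed)
    df = seed_table.counts
    groups = _balanced_groups(rng, df.columns)
    if design.diff_pool == "all_taxa":
        pool = df.index
    else:
        pool = df.index[seed_table.prevalence() >= PREVALENT]
    injected, diff = _inject_fold_change(
        df, groups, rng, design.n_diff, design.fold_change, pool
    )
    return CountTable(injected, groups), SimulationTruth(
        groups, diff, design.fold_change
    )


#: distributional targets of the download-free stand-in seed tables; these
#: emulate the shape (dimensions, sparsity) of published gut datasets, not
#: their actual counts
SEED_PROFILES = {
    "wu_like": dict(n_taxa=400, n_samples=98, log_sd=2.5, precision=5.0),
    "brito_like": dict(n_taxa=77, n_samples=112, log_sd=1.2, precision=50.0),
}


def synthetic_seed_table(profile: str = "brito_like", seed: int = 0) -> CountTable:
    """Synthetic stand-in seed table with a heavy-tailed taxon profile.

    ``wu_like``: 400 taxa x 98 samples, log-normal(sd 2.5) concentration
    profile at total precision ~5 — a sparse table with many low-prevalence
    taxa.  ``brito_like``: 77 taxa x 112 samples, milder tail (sd 1.2,
    precision ~50) with a sizeable core of highly prevalent taxa.  Depths
    are NB(10,000, 25).
    """
    if profile not in SEED_PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    cfg = SEED_PROFILES[profile]
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=cfg["log_sd"], size=cfg["n_taxa"])
    conc = raw / raw.sum() * cfg["precision"]
    taxa = [f"t{i:03d}" for i in range(cfg["n_taxa"])]
    params = DirichletMultinomialParams(pd.Series(conc, index=taxa))
    design = SimulationDesign(
        n_samples=cfg["n_samples"],
        n_taxa=cfg["n_taxa"],
        n_diff=0,
        fold_change=1.0,
        seed=int(rng.integers(2**31)),
    )
    table, _ = generate_parametric(params, DepthModel(), design)
    return CountTable(table.counts)
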