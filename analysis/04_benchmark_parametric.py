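#!/usr/bin/env python
"""Parametric benchmark: the sparsity-driven power collapse.

Fits a Dirichlet-multinomial to the sparse wu-like seed table and simulates
from it, drawing differential taxa uniformly from *all* taxa.  Because most
taxa are rare, fold-change injection leaves their many zero counts (and
hence their ranks) unchanged, and rank-test power collapses - in contrast
to the non-parametric scheme restricted to prevalent taxa.
"""

from pathlib import Path

from cortree import evaluate

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20200415


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records, summary = evaluate.run_benchmark(
        procedures=("bh",),
        fold_changes=(5.0, 10.0, 15.0, 20.0),
        n_diffs=(40,),
        replicates=25,
        scheme="parametric",
        seed_profile="wu_like",
        diff_pool="all_taxa",
        alpha=0.05,
        seed=SEED,
    )
    records.to_csv(OUT / "benchmark_parametric_records.tsv", sep="\t", index=False)
    summary.to_csv(OUT / "benchmark_parametric_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(
        f"\nmean TPR {summary['tpr_mean'].mean():.3f} - an order of magnitude "
        "below the non-parametric benchmark: multiplying zeros by a fold "
        "change changes nothing, so sparse differential taxa are invisible "
        "to rank tests."
    )


if __name__ == "__main__":
    main()
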