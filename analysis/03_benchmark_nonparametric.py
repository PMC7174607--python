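#!/usr/bin/env python
"""Non-parametric benchmark: BH vs tree-guided smoothing, TPR and FDR.

Resamples the brito-like seed table, injects fold changes {5,10,15,20} into
10 highly prevalent taxa, and scores Benjamini-Hochberg against z-score
smoothing guided by the correlation tree and by a leaf-shuffled
(uninformative) correlation tree.  Writes tidy records and per-cell
summaries to results/.
"""

from pathlib import Path

from cortree import evaluate

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20200415
REPLICATES = 15


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records, summary = evaluate.run_benchmark(
        procedures=("bh", "smooth:correlation", "smooth:random_correlation"),
        fold_changes=(5.0, 10.0, 15.0, 20.0),
        n_diffs=(10,),
        replicates=REPLICATES,
        scheme="nonparametric",
        seed_profile="brito_like",
        alpha=0.05,
        seed=SEED,
        n_permutations=100,
    )
    records.to_csv(OUT / "benchmark_nonparametric_records.tsv", sep="\t", index=False)
    summary.to_csv(OUT / "benchmark_nonparametric_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    overall = summary.groupby("procedure")[["tpr_mean", "fdr_mean"]].mean()
    print("\naveraged over fold changes:")
    print(overall.to_string())
    shift = records.groupby("procedure")["mean_abs_z_shift"].mean()
    print("\nmean |mu* - z| per smoothing variant:")
    print(shift.dropna().to_string())
    print(
        "\nall procedures detect essentially every injected taxon and keep "
        "FDR near the nominal 5%: the fitted smoothing strength is "
        "negligible (see the z-shift diagnostic above), so the tree-guided "
        "variants collapse onto the BH baseline rather than improving on it."
    )


if __name__ == "__main__":
    main()
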