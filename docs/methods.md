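# Methods

## Data model

The universal input is a taxa × samples table of non-negative integer counts
with an optional sample → group mapping (`cortree.io.CountTable`). Taxa with
prevalence (fraction of samples with count > 0) below a threshold can be
filtered; the comparison is inclusive (≥) and defaults to 5%. Trees are
`skbio.TreeNode` objects read from newick; taxonomic trees are built from
rank-ordered lineage tables, with each branch length equal to the number of
hierarchy levels it spans (missing intermediate ranks are skipped, so a
branch may span several levels).

## Correlation tree

Pairwise Spearman correlation is computed after removing "shared zeros"
(samples where both taxa are absent): double absences carry no information
about co-variation and would otherwise inflate correlations among rare taxa.
Degenerate pairs — fewer than 3 usable samples, or a constant restricted
vector — get correlation 0, i.e. dissimilarity 1 ("uninformative"); this
keeps the dissimilarity matrix total and symmetric. Ties use mid-ranks.

The dissimilarity 1 − ρ̂ ∈ [0, 2] is clustered with Ward linkage. Two Ward
variants exist in common software; the default `ward_d2` applies the
Lance–Williams recurrence to squared dissimilarities (scipy's `ward`,
R `hclust ward.D2`), `ward_d` applies it to the raw dissimilarities
(R `ward.D`, obtained here by running scipy's ward on √d and squaring the
merge heights). Both are cross-checked against R's `hclust` in the test
suite. Merge-cost ties are resolved by scipy's deterministic ordering.
The dendrogram is ultrametric with node height = merge cost / 2, so the
patristic distance between two leaves equals their cophenetic merge cost.

Bootstrap forests resample sample columns with replacement (taxa fixed) and
rebuild the correlation tree; random forests shuffle leaf labels of a seed
tree, preserving topology and the branch-length multiset exactly — which
keeps RF distances comparable, since RF scales with the number of splits.
Forest sizes default to 100 and are configurable.

## Treespace distances

Trees are compared as unrooted weighted trees; a bifurcating root's two
edges merge into one. RF distance is the symmetric difference of the
non-trivial split sets, reported unnormalized.

BHV distance treats pendant edges as always-shared coordinates. The GTP
algorithm starts from the single support pair (A, B) of incompatible splits
and repeatedly solves, for each pair (A_i, B_i), a minimum-weight vertex
cover of the bipartite incompatibility graph with weights ℓ(a)²/‖A_i‖² and
ℓ(b)²/‖B_i‖², via max-flow/min-cut (scipy). A cover of weight < 1
(tolerance 1e-12) splits the pair into (C_A, B_i∖C_B), (A_i∖C_A, C_B);
pairs whose splits have no incompatibilities separate into independent
coordinates. The geodesic length is
√(Σ_shared (Δℓ)² + Σ_pendant (Δℓ)² + Σ_i (‖A_i‖+‖B_i‖)²). The
implementation is validated against an independent oracle that enumerates
every admissible support sequence (compatibility of later A-blocks with
earlier B-blocks, non-decreasing norm ratios) on random 4–6-leaf tree pairs,
and against metric/bound properties (≥ shared-split Euclidean part, ≤ cone
path, = Euclidean when topologies agree, triangle inequality).

PCoA double-centres −d²/2 and eigendecomposes; negative eigenvalues are
dropped (no Cailliez/Lingoes correction) and explained variance uses the
positive part only. The bootstrap confidence region uses the empirical
level-quantile with linear interpolation between order statistics (numpy
default, type 7); membership at the boundary depends on this choice, which
is why it is pinned. The distance-group comparison is a textbook one-way
ANOVA with an ε-guard: identical groups report F = 0, p = 1; complete
separation with zero within-group variance reports F = ∞, p = 0.

## Differential-abundance tests

Wilcoxon rank-sum for two groups (exact two-sided null when both groups
have ≤ 10 samples and the taxon has no ties, otherwise the normal
approximation with tie correction), Kruskal–Wallis or the one-way ANOVA
F-test for more. Constant taxa get p = 1 rather than NaN. z-scores use the
lower-tail convention z = Φ⁻¹(p) with p clamped to [1e-15, 1−1e-15], so
strong evidence means very negative z and every downstream rejection region
is a lower tail. BH adjustment is the standard step-up (statsmodels),
cross-checked against the literal definition on exhaustive p-grids.

TSS (relative abundance) and TMM normalization are provided. The TMM
factors follow the trimmed-mean-of-M-values recipe — reference sample by
upper quartile closest to the mean, 30%/5% M/A trims, precision-weighted
mean of the remaining log-ratios, geometric-mean-1 normalization — and
reproduce `edgeR::calcNormFactors` to 6 decimals in a cross-check test.

**Normalization in the simulation benchmark.** The simulated designs draw
sequencing depths identically in both groups, so rank tests on raw counts
are exactly calibrated there, and the benchmark defaults to
`normalization="none"`. Rescaling per sample *after* fold-change injection
is actively harmful in this design: the injected prevalent taxa carry a
large share of group-B reads, so TSS — and even TMM, once the changed taxa
exceed its trimming breakdown point — redistributes the inflation onto null
taxa and inflates the FDR several-fold. Real datasets with systematic depth
differences between groups should use TMM/TSS, which the real-data entry
points default to.

## z-score smoothing (vanilla, no fallback)

The hierarchical model z|μ ~ N(μ, σ²I), μ ~ N(γ1, τ²C_ρ),
C_ρ = exp(−2ρD) on the patristic matrix D. The MAP estimator
μ\* = (I + kC_ρ⁻¹)⁻¹(kC_ρ⁻¹γ1 + z) is computed through the algebraically
identical SPD system (C + kI)μ\* = Cz + kγ1 — C⁻¹ is never formed — with a
1e-10 jitter and failure declared when the condition estimate exceeds 1e12.

Hyperparameters are fitted by maximizing the marginal likelihood
z ~ N(γ1, σ²I + τ²C_ρ): ρ runs over a 40-point log grid spanning
[10⁻³, 10³] / median nonzero patristic distance; for each ρ the likelihood
is profiled over k = σ²/τ² (bounded 1-D optimization in log k), with γ the
GLS mean and τ² the closed-form residual scale. Because C_ρ → I makes k
unidentifiable (the likelihood becomes flat in k), the structured fit must
beat the iid model z ~ N(γ, s²I) by an AIC margin (2 log-likelihood units
for its two extra parameters); otherwise the fit collapses to the
no-smoothing solution k ≈ 0, under which μ\* = z. This guard reproduces the
known empirical regime of the method — little to no smoothing on data whose
tree carries no signal — and is exercised by the null-model tests.
Parameter recovery (k within a factor 2, γ within ±0.2 on medians) is
verified on 100-leaf simulated data.

FDR control is by permutation: group labels are permuted (group sizes
preserved), (ρ̂, k̂) stay fixed at the observed fit while γ is re-estimated
per permutation (a flag disables re-estimation), and
FDR̂(t) = mean_b #{μ\*_b ≤ t} / max(1, #{μ\* ≤ t}) over the observed μ\*
values as threshold grid; rejection at the largest t with FDR̂ ≤ α. There is
no fallback to unsmoothed tests. Numerical failures raise a status the
benchmark records as a per-replicate failure rate, never retried silently.

## Hierarchical FDR

Internal nodes test the per-sample sum of (normalized) descendant
abundances; the root carries no hypothesis, so the first family is the
root's children. Families are processed breadth-first (the result is
traversal-order independent because family tests are independent), each
with BH at the within-family α; children of non-rejected nodes are never
tested. `#discoveries` in the a-posteriori bound
α′ = 1.44·α·(D + F)/(D + 1) counts leaf-level discoveries, pinned by the
worked example (3 leaves, 5 families → multiplier 2); every BH invocation —
including singleton families — counts as one family. On a star tree the
procedure is exactly BH on the leaf p-values, which is tested. Default
normalization for hFDR is TSS, with `none` available to reproduce tools
that ignore depth differences.

## Synthetic data

The parametric scheme fits a Dirichlet-multinomial by method of moments
(mean proportions × precision; precision (1−θ)/θ from the average
overdispersion θ of proportion variances) and then draws, per sample,
proportions ~ Dirichlet, depth ~ NB(mean 10,000, size 25; variance
μ + μ²/size = 4.01·10⁶), counts ~ Multinomial. The non-parametric scheme
uses a seed table verbatim. In both, samples are split into exactly
balanced groups by random permutation (not coin flips), n_diff taxa
(capped at 20% of taxa unless overridden) are drawn uniformly from the
design's pool — all taxa for the parametric scheme, prevalence ≥ 0.9 for
the non-parametric one — and group-B counts are multiplied by the fold
change (integer folds exact; non-integer folds round half-to-even).
Everything is deterministic under the design seed, truth sets included.

Two download-free seed tables emulate the *shape* of published gut
datasets, not their counts: `wu_like` (400 taxa × 98 samples, log-normal
sd 2.5 concentration profile, precision 5 — very sparse, median prevalence
~1%) and `brito_like` (77 × 112, sd 1.2, precision 50 — a dense core with
≳30 taxa above 90% prevalence). The log-sd/precision values are calibration
knobs chosen so the sparsity profiles produce the two benchmark regimes
(rank tests powerless on injected zeros vs near-full power on prevalent
taxa); they are synthetic stand-ins, and results on them say nothing about
the real datasets beyond those regimes. The parametric generator inherits
the Dirichlet-multinomial's limitation of only negative inter-taxon
correlations, so correlation-tree structure in parametric data is weaker
than in real tables.

## Benchmark

Each replicate regenerates groups, differential taxa, the correlation tree
(from that replicate's table) and any random tree (fresh shuffle). TPR is
|detected ∩ truth|/|truth| (undefined, and excluded from means, when there
are no differential taxa); FDR is |detected ∖ truth|/max(1, |detected|), so
an empty discovery set scores 0. Cells report mean, SEM = sd/√n_ok over
non-failed replicates, and the failure rate. The default grid (fold changes
{5,10,15,20}, 10 differential taxa of 77, α = 0.05) runs 50–100 replicates
per cell in the acceptance checks and 15 in the analysis scripts — sizes
chosen so the full default benchmark completes in minutes on one CPU; SEMs
are reported so the Monte-Carlo resolution is explicit. The "taxonomy"
variant of the published study requires a real taxonomy, which the
synthetic stand-ins do not have; the benchmark therefore compares BH with
smoothing guided by the correlation tree and by leaf-shuffled
(uninformative) trees.

## Known limitations

* The real-data reanalyses need the public datasets
  (`scripts/fetch_external.py`); nothing is bundled, and the corresponding
  acceptance check fails without them. Reproduction of published discovery
  counts also depends on matching the upstream tools' per-node test choices.
* The GTP implementation targets trees of a few hundred leaves; the
  all-pairs BHV matrices in the treespace script are the slow path.
* The hyperparameter fit is a grid-profile estimator, not the original GLS
  implementation, whose exact form is unspecified; its behavior is pinned
  by recovery and null-model tests instead.
* hFDR's theoretical guarantee assumes independence between a node's
  p-value and its ancestors', which aggregation violates in practice; α′ is
  reported as the bound it is, not as an achieved FDR.
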