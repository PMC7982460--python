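# Methods

This note documents the statistical machinery of `irgpairs`: what each stage
assumes, which knobs matter, what the synthetic cohorts do and do not
emulate, and the numerical choices that were genuinely open.

## The gene-pair feature space

The elementary feature is the within-sample comparison `I_ab(s) = 1 iff
x_a(s) > x_b(s)`, with ties scored 0 (the literal "otherwise 0" rule). Two
conventions fix the feature space uniquely:

* **Canonical enumeration.** `build_pairs` enumerates all unordered pairs in
  lexicographic orientation (gene_a < gene_b), so the matrix is independent
  of input gene order. A *model file*, however, stores its own (irg1, irg2)
  orientation and the scorer honours it as-is — flipping an orientation
  negates the meaning of its coefficient, so published coefficients must
  travel with their published orientation.
* **Imbalance filter.** A pair whose minority state occurs in fewer than 20%
  of samples carries little information and is removed; the boundary is
  closed (exactly 20% is kept) and the fraction is computed from integer
  counts so the boundary is exact. Constant pairs (MAD = 0) are the special
  case with minority fraction 0; a single filter subsumes both published
  phrasings.

Because only within-sample ranks enter, the features — and any risk model
built on them — are invariant to per-sample monotone transforms. This is the
property the test suite asserts with randomised monotone maps, and the
reason a model fitted on one platform can be scored on another.

## Differential expression

`moderated_de` is a two-group moderated t-test: per-gene pooled variances
are shrunk toward a prior estimated from all genes. The prior (d0, s0²) is
fitted by method of moments on log sample variances: with
`e_g = log s_g² − digamma(d/2) + log(d/2)`, the excess of `Var(e)` over
`trigamma(d/2)` equals `trigamma(d0/2)`, inverted by Newton's method; the
posterior variance is `(d0·s0² + d·s²)/(d0 + d)` and the t statistic gains
d0 extra degrees of freedom. When the observed log variances are no more
dispersed than sampling noise allows, d0 is infinite and the common variance
s0² is used with a normal reference. The implementation was validated to
5e-12 against the reference empirical-Bayes fit (R limma) on a frozen
fixture, which the test suite replays. DE calls use |log2FC| > 0.5 and
BH-adjusted p < 0.05 by default; log2FC is the difference of group means on
log2 data (direction: lexicographically larger group minus smaller,
configurable via `reference`).

## Per-sample signature scores

`ssgsea_score` is single-sample GSEA: per sample, genes are ranked by
expression and the score is the summed difference between the weighted
in-set ECDF (weights = rank^0.25, the original ssGSEA exponent) and the
uniform out-of-set ECDF. No cross-sample normalisation is applied because
downstream consumers (group contrasts, module–trait correlations) are
invariant to it. Scores are computed on all genes, not only DEGs.

## Co-expression modules

The WGCNA core uses unsigned power adjacency `|cor|^β`. The soft threshold
scan computes, for each β, the signed scale-free fit index
`−sign(slope)·R²` of the log–log regression of binned connectivity
frequencies (10 equal-width bins, bin mean as the representative degree).
The smallest β reaching R² ≥ 0.9 is chosen; when no power reaches the
target — which is the norm for block-structured correlation, whose degree
distribution is bimodal rather than scale-free — the scan falls back to the
standard sample-size default for unsigned networks (6 at ≥ 40 samples, 8/9/10
below 40/30/20) rather than the meaningless argmax, which lands on
arbitrarily large powers and erases the network.

TOM follows the standard formula
`TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)` with unit
diagonal; the implementation is checked against a brute-force triple loop at
1e-10. Modules come from average-linkage clustering of `1 − TOM` with a
*static* cut at a fraction of the dendrogram merge-height range; clusters
below `min_module_size` (default 30) are relabelled grey. The default cut
fraction is 0.7: on synthetic cohorts with four planted modules the
inter-module merges sit in the upper ~25% of the height range, so cutting at
0.6–0.8 recovers the planted partition exactly while cutting near the top
fuses modules with background noise. The dynamic hybrid tree cut and
eigengene-based module merging are intentionally out of scope.

Eigengenes are first principal components of the standardized module
expression (unit norm over samples), sign-oriented to correlate positively
with the module's mean profile. MM is the gene–eigengene correlation, GS the
signed gene–trait correlation; the screen keeps module genes with |MM| > 0.5
and |GS| > 0.5. An alternative GS convention (−log10 p of the gene–trait
regression) exists in the literature but is inconsistent with a 0.5
threshold on the correlation scale; it is exposed via
`screen_genes(..., gs_method="neglogp")` and is not the default.

## Survival modelling

*Univariate screen.* Every pair indicator gets a single-covariate Cox fit
with the Efron tie correction, Newton-iterated to gradient < 1e-8. The
solver is batched across pairs (a binary covariate satisfies x² = x, so two
weighted suffix sums per iteration suffice) and is cross-checked in the
tests against lifelines and against direct numerical maximisation of the
same partial likelihood. Pairs with Wald p < 0.05 proceed.

*Lasso-Cox.* The penalty path comes from coxnet (scikit-survival); the
penalty is chosen by repeated K-fold cross-validation: for each of
`n_repeats` random fold assignments the held-out partial-likelihood deviance
is computed by the full-minus-train construction, and the penalty minimising
the mean deviance is refit on all data. "1000 simulations" of the original
analysis is read as 1,000 fold randomisations; the repeat count is a compute
knob (tests use 25, the pipeline default is 1000). The minimum-deviance rule
is the default — the published selection (16 pairs of 69 candidates) implies
a permissive penalty — with the parsimonious 1-SE rule exposed for support
recovery questions.

*Risk score and cutoff.* `RS = Σ β_k I_k`; the dichotomization cutoff comes
from the time-dependent ROC at a fixed horizon: cumulative cases (event by
t), dynamic controls (still at risk after t), sensitivity/specificity by the
Kaplan–Meier-weighted estimator within score strata (the survivalROC "KM"
construction, which reduces exactly to the empirical ROC when censoring is
absent — asserted in the tests), AUC by trapezoid on the monotonized path,
optimal cutoff by Youden's J with ties resolved to the lower threshold.
Classification is strictly-greater: `RS > cutoff → high risk`, so a sample
sitting exactly on the cutoff is low risk. A transferred model's cutoff is
applied unchanged on validation cohorts.

*Group comparison and adjustment.* KM curves and the log-rank test are
lifelines'; multivariate Cox (risk score plus clinical covariates, Efron
ties) likewise. `maxstat_cutpoint` scans observed marker values inside a
quantile window (default 10–90%) and returns the cutpoint maximising the
two-group log-rank chi-square; no p-value approximation for the maximally
selected statistic is provided because only the cutpoint is consumed
downstream.

## Deconvolution

`deconvolve` regresses each sample's signature-gene expression (linear
scale; `from_log2=True` un-logs) on a genes × cell-types signature matrix by
non-negative least squares and normalises coefficients to fractions. It is a
deterministic, assumption-light estimator in the same reference-based family
as ν-SVR approaches; the signature matrix is a user input. Confidence per
sample is a Monte-Carlo permutation p: the sample's expression values are
randomly reassigned to genes `n_perm` times (default 100, add-one smoothed,
so min p = 1/(n_perm+1)) and p is the fraction of permutations whose
reconstruction correlation reaches the observed one. Samples with p ≥ 0.05
are dropped before per-cell-type Wilcoxon rank-sum comparisons between risk
groups.

## Enrichment and key genes

Preranked GSEA ranks genes by the difference of group mean log2 expression
(high minus low risk). ES is the weighted KS running sum (weight 1 by
default; weight 0 gives the classic KS statistic); the null is gene-label
permutation at matched set size, NES divides ES by the mean |null ES| of the
same sign, p is the matching-sign permutation tail with add-one smoothing,
and FDR is BH across sets (a simplification of the NES-matched GSEA FDR).
ORA is the hypergeometric upper tail. Hub genes are vertices of a
user-supplied interaction edge list with degree strictly greater than 10
(self-loops ignored, duplicate edges collapsed); intersecting hubs with the
risk model's gene union nominates key prognostic genes.

## The synthetic cohorts

`generate_cohort` plants exactly the three structures the pipeline is built
to find, on log2 scale directly (no count model is assumed):

* **DE block** — the first `n_de_genes` genes gain `de_log2fc` in the
  "right" arm.
* **Modules** — `n_modules` blocks of `module_size` genes, each a latent
  factor model `x = loading·f_m + noise` calibrated so the within-module
  correlation is `within_module_cor`; one factor is recorded as the true
  immune score. Module blocks are nested inside the DE block so the
  DEG → module funnel is non-empty.
* **Survival** — exponential proportional hazards with linear predictor
  `Σ β_k I_k` over planted pair indicators (same tie rule as inference),
  independent exponential censoring with rate `censoring_rate`. Planted
  pairs are the first genes of the immune module, deterministically, so
  cohorts drawn from the same spec at different seeds share the prognostic
  structure and fit-then-validate experiments are meaningful.

Defaults (200 samples/arm, 2,000 genes, 600 DE, four 100-gene modules,
within-module correlation 0.7, pair log-hazards ±0.8–1.0, baseline hazard
0.05, censoring rate 0.03, noise SD 0.5 log2 units) give roughly 70%
observed events and recoverable but not trivial signals at desk scale.

What the generator does **not** emulate: batch and platform effects, count
noise (mean–variance coupling), correlated censoring, real gene symbols,
heavy-tailed hub-gene degree distributions (its modules are homogeneous
blocks — the reason the scale-free target is unreachable, see above), or
overlap between the immune module and deconvolution signatures. Passing
recovery tests therefore demonstrates correctness of the machinery under
the stated model, not performance on real cohorts.

## Problem sizes and determinism

The test suite runs recovery experiments at the generator defaults with
10–20 seeds per claim and reduced cross-validation repeats (25); the
end-to-end fit-then-validate check uses 10 repeats and 5 folds per seed.
All randomness flows through `numpy.random.default_rng` seeded per run;
identical (spec, seed) pairs reproduce byte-identical cohorts, and the
pipeline manifest records every count and threshold that shaped an output.

## Known limitations

* The static tree cut needs a sensible `cut_height`; very unequal module
  sizes or correlations may require tuning where the dynamic hybrid cut
  would adapt.
* The KM-weighted time-dependent ROC estimator is not guaranteed monotone
  under heavy censoring; the reported curve is the monotonized path.
* BH-based GSEA FDR across sets is simpler and slightly more conservative
  than the NES-matched permutation FDR.
* NNLS deconvolution has no outlier robustness; grossly contaminated
  samples should be caught by the permutation confidence filter, not the
  fit itself.
* `lasso_cox_select` with 1,000 repeats on thousands of pairs is the one
  genuinely expensive call; repeats parallelise trivially in user code if
  needed (the package keeps it single-threaded and deterministic).
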