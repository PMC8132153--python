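# Methods

## The model

The classifier treats chemotherapy non-response as the positive outcome
of a binomial logistic model over binary mutation indicators. For a
patient with mutation profile `x ∈ {0,1}^G` over the model genes, the
risk score is the linear predictor

    score(x) = β₀ + Σ_g β_g x_g

on the log-odds scale, and the patient is called a non-responder when
`score(x) ≥ c`, with `c` chosen by the maximum Youden index
(`J = sensitivity + specificity − 1`) on the training ROC. A score
exactly at the cutoff is classified non-responder; this boundary
convention is arbitrary but fixed. The published 15-gene model has
near-separating coefficients (≈ 20 log-odds units for eleven of the
fifteen genes), so any mutation in a large-coefficient gene dominates
the score; the four small-coefficient genes (SALL3, ANKDD1B, BCL9L,
VPS13C) can never exceed the 8.4 cutoff on their own (their maximal
combined score is 8.1). An alternative published decision rule —
non-responder if *any* model gene is mutated — is available behind the
`any_mutation` flag, but the score/cutoff rule is canonical; the two
disagree exactly on the small-coefficient-only profiles.

## Candidate selection

**Enrichment filter.** Per gene, a 2×2 table of mutation by response is
tested with the two-sided Fisher exact test (sum of hypergeometric
probabilities ≤ that of the observed table — the conventional exact
two-sided definition; a doubling convention exists but is not used).
Genes pass with `mut_insen − mut_sen ≥ 2` and `p < 0.25` (strict).
The p-threshold is deliberately permissive and unadjusted: this stage
is a screen, not an inference. Odds ratios use the Haldane–Anscombe 0.5
correction on all four cells whenever any cell is zero. Variants with
population allele frequency above 0.01 are removed as presumed
germline; a missing frequency is kept, because the filter exists to
remove *known*-common variants. Unrecognized variant-classification
strings warn and count as silent.

**Screen filter.** Counts are normalized with median-of-ratios size
factors computed over sgRNAs nonzero in every column (a pseudocount
option rescues sparse libraries). Note the factors are defined relative
to each sgRNA's geometric mean across columns, so scaling one of *m*
columns by *c* multiplies that factor by `c^(1−1/m)` — factor *ratios*
scale by `c`, and normalized counts change only by a global constant,
which is what fold changes depend on. Gene-level values are the mean of
normalized counts over the gene's sgRNAs within each replicate (the
aggregation the screen design implies but does not pin down); the fold
change is the ratio of treated to control replicate means, with a 0.5
pseudocount substituted (and flagged) when the control mean is zero.
P-values come from a pooled-variance two-sample t-test on
log2(gene-level count + 0.5) across replicates: Student's rather than
Welch's form, because at three replicates per arm the pooled test has
the only usable degrees of freedom. These are decision variables for
hit selection, not calibrated error rates. The two-tier rule reads all
fold thresholds on the linear scale (the companion 1.32 threshold makes
any log-scale reading impossible). The condition→criterion mapping is
configurable because the screen design applies tier (i) to the
single-drug arms and tier (ii) to arms that overlap them; defaults are
tier (i) = (DDP, Taxol), tier (ii) = (Taxol, DDP+Taxol).

## The penalized cascade

Three repeated penalized logistic stages run in order — ridge, elastic
net (mixing 0.5, configurable), lasso — each `n_reps = 200` times. A
repetition draws fresh stratified `cv_folds = 10` fold assignments from
the seeded stream (repetitions differ *only* in fold assignment, not in
patient resampling), scores a fixed log-spaced grid of penalty
strengths (default 10 points spanning C ∈ [10⁻², 10²]) by
cross-validated mean squared error of predicted probabilities, refits
the winning penalty on the full data, and accumulates each gene's
coefficient when nonzero. Ridge produces no exact zeros, so in the
ridge stage every gene counts as nonzero; ranking is by absolute summed
coefficient everywhere ("according to the distribution" is read as
rank order, with no distributional fitting). Predictors are 0/1 and are
not standardized; the intercept is unpenalized. Retention keeps the top
80% / 90% / 75% of nonzero-ranked genes per stage (an explicit keep
count may be given instead — the printed stage sizes of the original
build, 744→222→58→32, do not match its printed fractions, and both
options are therefore exposed). Repetitions that fail to converge are
excluded; more than 20% failures aborts the stage.

After each stage, and twice more before the final build (the
"co-occurrence checks"), a Spearman prune removes collinear genes:
among all pairs with |r| ≥ 0.5 the worst pair is resolved first by
dropping the member with the smaller absolute summed coefficient, and
correlations among survivors are re-examined until no pair exceeds the
threshold. Constant columns correlate with nothing (NaN → 0).

## The greedy build

Candidates enter ranked by their lasso-stage rank. The top two are
fixed. Each step refits the logistic model with every remaining
candidate added and scores it by pooled out-of-fold AUC over one
stratified fold assignment drawn once from the seeded stream and reused
for every comparison (so candidates are compared on identical splits).
Ties within 10⁻¹² of the best AUC are broken by better lasso rank, then
by fewer positive Spearman correlations ≥ 0.5 to the other candidates;
all candidates tied at the winning AUC are permanently discarded at
that step (retrying them later is the other defensible reading; the
discard-at-step rule is the one implemented). The search stops when no
candidate strictly increases the AUC. Final coefficients come from an
unpenalized maximum-likelihood fit on the full training set; under
(quasi-)separation — which binary predictors at n = 56 invite — the fit
falls back to a small ridge stabilizer and the model provenance records
it. No attempt is made to reproduce the published ≈20-unit
coefficients from data: they are themselves signatures of separation.

The clinical classifier is the same logistic machinery over age
(dichotomized at the cohort median), dummy-coded stage and
differentiation, and log SCC-ag; samples with any missing covariate are
excluded, covariates constant afterwards are dropped with a warning.

## Evaluation

Non-responder is the positive class throughout. Each percentage metric
carries a binomial standard error `100·√(p(1−p)/m)` on its own
denominator `m`; a zero denominator yields an undefined metric, never
zero. AUC inference uses the DeLong placement-value variance with
z = 1.96 intervals and a normal z-test against 0.5 (the published
per-row p-values' exact construction is undocumented; the z-test is
provided without claiming to match them). Odds ratios are
cross-products with Wald log-scale intervals, Haldane-corrected on zero
cells; the univariate logistic odds ratio for a single binary predictor
equals this cross-product by MLE identity, which the tests exploit.
Logistic association fits fall back to a ridge-penalized IRLS (penalty
α = 1, intercept unpenalized, Wald errors from the penalized
information matrix) under separation, flagged in the result.

## The synthetic-data generator

Cohort entries are independent Bernoulli draws: planted "resistance"
genes use group-specific mutation probabilities, all other genes a
shared background rate (default 0.03, a plausible per-gene non-silent
rate for exome-scale candidates). Cohort shapes default to the study's:
30/26 training, 22/80 validation. An optional pairwise-correlation knob
makes consecutive planted genes share events, solely to exercise the
pruning stages. Clinical covariates are drawn per group with a
dichotomized-latent tilt: a stated effect is the log-odds contrast for
the "high" state (old age, advanced stage, poor differentiation, high
SCC-ag) between non-responders and responders. Screen counts are
negative-binomial (dispersion α, variance μ + αμ²; α = 0 degenerates to
Poisson) with uniform baseline library representation (default mean
500), lognormal per-column depth variation (σ = 0.15) so normalization
is non-trivial, and treated-arm means multiplied by each enriched
gene's fold.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: mutational covariance
structure beyond the optional knob, per-sample mutation-burden
heterogeneity (the real cohort's burden distribution is unreported),
panel-level artifacts (FFPE damage, purity, coverage), sgRNA-level
efficacy differences within a gene, and any relationship between
clinical covariates and mutations. Recovery results on synthetic
cohorts are statements about the pipeline's correctness under its own
model, not about clinical performance.

## Problem sizes and numerical choices

The default cascade (200 repetitions × 10 folds × 10 penalties) is the
published protocol; `SelectionConfig.reduced()` (8 repetitions, 5
folds, 8 penalties) is the profile used by the test suite, the example
configuration and the acceptance script, where the cascade runs many
times over — with the strong planted effects of the simulation studies
(mutation probability 0.5 vs 0.05 at n = 200/200) the reduced profile
recovers the planted genes as reliably as the full one. Determinism is
end-to-end: every stage draws its seed from one `numpy` Generator
seeded at the top, and identical configuration + seed reproduces every
artifact bit-exactly. Penalty-grid ties resolve to the strongest
penalty; rank ties resolve to input gene order; Youden ties resolve to
the smallest threshold, evaluated at midpoints between adjacent
distinct scores.

## Known limitations

- The original p-values of the screen analysis came from a
  negative-binomial differential framework; the t-test substitute keeps
  the same decision variables but not the same p-values (which are
  unreproducible regardless, as no screen data are deposited).
- The elastic-net mixing parameter, the condition→criterion mapping of
  the screen rule, and the retry policy for AUC-tied candidates are
  genuinely underdetermined by the published description; each has a
  documented default and a configuration point.
- Cohort-dependent published results (training AUC 0.93, validation AUC
  0.80, the 744→222→58→32→27→15 stage sizes, the 8.4 cutoff) depend on
  undeposited patient-level data and are not reproduction targets; the
  package instead verifies every printed identity that is derivable
  (Table-row metrics, SEs, odds-ratio intervals, risk-score formula)
  and validates the machinery by oracle equivalence and planted-signal
  recovery.
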