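# Methods

## Problem setting

A case-control neuroimaging contrast (healthy controls vs schizophrenia
patients) is learned from subject-by-region feature tables and then
interrogated in three ways: is the cross-validated accuracy better than
chance (permutation inference); do members of an independent family cohort
carrying a risk variant resemble the patient class (transfer prediction
with contingency inference); and are the predictive probabilities
explained by nuisance variables (screened correlations). All stages run
equally on real tables (CSV/TSV) and on synthetic cohorts.

## Classifier

Binary Gaussian-process classification with a linear kernel
`k(x,x') = σ_f² xᵀx'` and cumulative-Gaussian (probit) likelihood.
Posterior inference is Expectation Propagation (EP): probit sites are
moment-matched in fixed ascending order until the largest site-parameter
change falls below 1e-6 (default; max 100 sweeps), with the posterior
recomputed from a Cholesky factor of `B = I + S½KS½` after every sweep for
numerical stability. Negative site precisions are clipped to zero so site
variances stay nonnegative. If EP fails to converge or loses positive
definiteness, the fit falls back to a Laplace (mode + curvature)
approximation; the fitted model records which route was used. A jitter of
1e-8 is added to the training Gram diagonal.

EP-with-probit was chosen because it yields analytic predictive
probabilities, `P(+1|x*) = Φ(μ*/√(1+σ*²))`, and is the standard
well-conditioned pairing for linear-kernel GP classification; the linear
kernel makes the latent mean an exact linear functional, giving the weight
map `w = σ_f² Xᵀα` with `μ*(x) = wᵀx` to machine precision.

**Hyperparameters.** One parameter, the signal variance `σ_f²`. Default is
fixed at `log σ_f² = 0`, appropriate for z-scored features; optionally it
is chosen by maximizing the EP evidence with bounded derivative-free
scalar search over `log σ_f² ∈ [−8, 8]` (tolerance 1e-6, ≤200
evaluations). A 1-D bounded search was preferred over gradient ascent:
the objective is cheap, unimodal in practice, and the evidence gradient
through the EP fixed point adds complexity without benefit. Whether
hyperparameters should be re-optimized per cross-validation fold is left
to the caller (`optimize_hyperparameters` flag); both modes are exposed
because common practice varies.

**Preprocessing inside folds.** Features are z-scored per feature using
training-fold statistics only; centering doubles as the offset handling
(the kernel has no bias term). Zero-variance training features are
centered but not scaled. Held-out subjects never contribute to their own
fold's statistics; transfer cohorts reuse the training statistics
unchanged.

## Cross-validation and permutation inference

pLOOCV holds out one age/sex-matched case-control pair per fold, keeping
every training fold balanced; LOOCV (single-subject folds) is used when
groups are unequal. Matching is greedy within sex: candidates are paired
to nearest age, ties broken by subject id, giving a deterministic
matching. Downsampling a larger group to a reference cohort allocates sex
slots proportionally (largest remainder, capped by availability) and cycles
through the reference ages, each claiming its nearest-aged unused
candidate.

In scheme B the noncarrier pool is downsampled to the number of carriers
plus two by default (capped at the pool size) — a mild imbalance that LOOCV
tolerates while keeping most of the matched material; the exact count is
configurable (`scheme_b_n_keep`).

The permutation test shuffles *training* labels only — within each
training fold, freshly per permutation round — refits, predicts the
untouched test subjects, and records the null accuracy. Whether labels
should be shuffled once per round or per fold is ambiguous in common
descriptions; per-fold shuffling is implemented as the stricter choice and
documented here. The p-value is the plain fraction
`#{null ≥ observed}/n_perm`, which can return exactly 0; the
`(count+1)/(n_perm+1)` convention is available behind a flag, default off,
to preserve the divide-by-n definition. Each permutation round draws its
RNG from a counter-derived child stream of the top-level seed, so results
are reproducible and order-independent. Class assignment thresholds
P(case) at 0.5, the symmetric point of the ±1 coding.

Accuracy is percent correct at that threshold; AUC is the Mann–Whitney
statistic of the predicted probabilities with ties counted one half.

## Transfer and inferential statistics

Scheme A refuses to transfer-test a contrast whose permutation p is ≥ 0.05
(configurable `alpha`); when significant, the model is refit on the full
training contrast and applied to the family groups and to the specificity
cohort. Assignments are tabulated 2×2 (true group × predicted class) and
tested with the two-sided Fisher exact test under the probability-mass
rule — the sum of hypergeometric probabilities of all margin-consistent
tables no more probable than the observed one. That convention is stated
explicitly because several two-sided definitions exist; the implementation
(scipy) is verified exhaustively against a full-enumeration oracle for all
tables with total ≤ 40.

Correlations between P(case) and covariates are Pearson product-moment
with the two-sided t-transform p (df = n−2). Influence screening computes
Cook distances on the full-data simple regression (intercept + slope,
p = 2), removes points with D > 0.5 in a single pass — no iteration — and
recomputes the correlation once on the remainder. Single-pass screening
mirrors the usual "remove and recalculate" reporting convention; the
closed-form D is verified against the n-refit leave-one-out definition.

The Wilcoxon signed-rank comparison drops zero differences (Wilcoxon's
original rule, as opposed to Pratt's), averages tied ranks, and uses the
exact sign-flip null for ≤ 25 tie-free informative pairs, otherwise the
normal approximation with continuity correction. No multiple-testing
correction is applied across modalities; contrasts are reported at their
nominal level.

## Synthetic cohorts

The generator draws
`value(s,r) = baseline_r + age_slope·(age_s − mid-age) + sex term +
group effect_r + family intercept + N(0, noise_sd_r²)`, with ages uniform
over the age range and sexes alternating within each group. Defaults
emulate regional cortical thickness: baseline 2.5 mm, residual SD 0.12 mm,
age slope −0.005 mm/year, sex offset −0.02 mm, ages 20–60, group sizes
24/24 cases/controls with 18 noncarriers and 12 carriers. The thinning
pattern is uniformly negative with temporal-lobe and precentral regions
boosted 1.5×; carriers receive the case effect scaled by
`carrier_effect_scale` (default 1), the bipolar specificity group by
`bp_effect_scale` (default 0). Residuals are independent across regions —
the simplest structure satisfying the analysis' assumptions; an optional
shared latent factor adds uniform spatial covariance (default off), and
one Gaussian intercept per family id models within-family correlation
(default SD 0).

What this emulates and what it does not: the generator reproduces group
mean structure, covariate confounding and family clustering, but not
realistic spatial covariance of cortical parcels, scanner/site effects,
heavy-tailed measurement noise, or missingness. Passing tests therefore
certify the machinery — fold hygiene, calibration of the permutation null,
recovery of injected effects — not performance on real MRI cohorts, whose
published accuracies depend on data unavailable here.

## Numerical and design choices

- Effect magnitudes in recovery tests: 0.36 mm thinning ≈ 3× the residual
  SD, the regime where near-perfect recovery is expected; null-calibration
  cohorts use zero effect.
- Problem sizes in the heavy simulations were chosen at desk scale: the
  type-I-error study uses 200 replicate cohorts of 8+8 subjects × 8
  regions at 99 permutation rounds; the acceptance calibration uses one
  24+24 × 68 cohort at 500 rounds.
- EP-vs-quadrature checks run at moderate latent amplitude (features
  scaled to 0.25): there the EP fixed point agrees with tensor
  Gauss–Hermite integration to under half the 1e-3 assertion, so the
  check tests implementation correctness with margin. At unit amplitude
  EP's intrinsic approximation error reaches a few 1e-3 on 2–3-point
  problems — a property of the approximation, not a defect.
- ICV normalization divides surface-area and subcortical-volume rows by
  each subject's eTIV; thickness and perfusion tables are guarded against
  it by modality. Perfusion rows are mean-scaled per subject; consensus
  feature masks are strict intersections.
- Missing cells are a hard error (complete-case analysis), as is a blank
  eTIV when normalization is requested.
- Report generation avoids timestamps so identical configurations
  reproduce byte-identical artifacts.

## Known limitations

Non-linear kernels, multiclass contrasts, k-fold/nested CV and
regression-based deconfounding are out of scope. The Fisher test and the
screened correlations assume independent subjects, which family data only
approximately satisfy. LOOCV-based accuracy estimates are high-variance at
these sample sizes; the permutation test accounts for this, but point
accuracies should be read with that in mind.
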