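# Methods

This note documents the statistical procedures implemented in
`symptomnet`, the defaults and why they were chosen, what the synthetic
cohort generator does and does not emulate, and the numerical edge cases.

## Change scores

Five per-item operationalizations of change between a baseline occasion
(session 1 = pretreatment assessment, or session 2 = first treatment
session) and the final session:

| method | formula | notes |
|---|---|---|
| FS | post | ignores the baseline values (kept as label metadata) |
| DS | post − pre | conserves the raw scores exactly |
| PC | 100·(post − pre)/pre | undefined at pre = 0 |
| RP | post − (a + b·pre) | a, b by OLS of post on pre |
| RC | DS − (a′ + b′·pre) | a′, b′ by OLS of DS on pre |

Because b′ = b − 1 and a′ = a under OLS on the same sample, RP ≡ RC; the
package verifies this identity numerically (`residual_identity_check`,
observed at ~1e−15). Residual scores have exactly zero sample covariance
with their baseline, which is the point: they remove regression to the
mean that a raw difference score retains.

Decisions:

- **PC at pre = 0** is marked missing and the row drops out of network
  estimation (complete-case), with a logged count. Any finite substitute
  (capping, imputation) is arbitrary and distorts the tails.
- **Residualizing regressions are pooled across arms** (never per arm):
  per-arm residualization would absorb the very treatment effect being
  estimated. When the network is fitted on a matched subsample, the
  regressions are refitted within that subsample, so the scores entering
  each model are orthogonal to baseline in that sample.
- **Constant baseline column**: slope 0, residual = centered outcome (the
  limit of OLS as predictor variance → 0). Fewer than 2 complete cases
  per item is an error.

## Node redundancy screen

Before network estimation, cross-sectional item scores at each timepoint
are screened for redundant node pairs: for a pair (i, j) with
|corr(i, j)| ≥ 0.5, every third node k yields a Williams-type test of the
dependent correlations corr(i, k) vs corr(j, k); the pair is flagged when
≥ 75% of the comparisons are non-significant (α = 0.05). The
minimum-pair-correlation guard is required for the screen to be
meaningful: without it, mutually independent items (whose correlation
profiles are all indistinguishably zero) would be flagged wholesale.

## Moderated network estimation

Nodewise regressions: node j's change score (standardized) on the other
15 standardized change scores, the raw 0/1 treatment indicator, and the
15 treatment × score products (not re-standardized, which preserves
arm-conditional additivity: arm-0 network = pairwise, arm-1 network =
pairwise + moderation). The treatment node is exogenous — it gets no
regression of its own — so direct associations come solely from the
symptom regressions and the AND rule applies only to symmetric
(pairwise, moderation) parameters.

- **Penalty selection**: elastic net with mixing parameter from
  {0.25, 0.5, 0.75, 1.0} and a 40-point penalty path, jointly selected by
  10-fold cross-validation at the minimum mean prediction error, with one
  fold assignment shared across all 16 regressions and derived from the
  run seed. The CV-minimum rule (rather than 1-SE) maximizes sensitivity
  to the small effects this analysis targets.
- **Post-selection thresholding**: CV-minimum lasso-type selection is not
  model-selection consistent; it retains many spurious coefficients whose
  magnitude is at the noise level. Following standard practice for
  nodewise graphical-model estimation, coefficients are zeroed when their
  standardized magnitude |coef|·sd(column) falls below
  τ = sqrt(2·log p / n) (p = number of predictors). The comparison is on
  the standardized scale because the treatment and product columns are
  not unit variance, so their raw coefficients overstate their
  standardized contribution. Measured effect on synthetic cohorts with a
  known 8-edge graph (n = 4000): false-positive rate drops from
  0.10–0.23 to ~0 with sensitivity still 1.0. Set `threshold=None` to
  disable.
- **AND rule**: edge (i, j) nonzero only if selected in both i's and j's
  regressions; weight = mean of the two coefficients, 0 on sign conflict.
- **Coefficient scale**: standardized-predictor scale throughout, the
  only scale on which edge weights are comparable across nodes.
- **Bootstrap**: case resampling with full refit (CV included) per
  resample; inclusion proportion and 2.5%/97.5% quantiles per parameter;
  resample-level failures are counted, not fatal. Deterministic given the
  seed.
- Constant outcome column → zero model with a warning; incomplete rows
  are dropped (complete-case) with the count recorded in `fit_meta_`.

## Propensity matching

Main-effects logistic model of treatment on: session-1 item scores,
gender, employment, psychotropic medication, age, ethnicity (indicator
coded) and baseline functional impairment. True perfect separation fails
with the separating covariate named; quasi-separation of rare indicator
levels (a handful of patients in one category) is tolerated because the
fitted probabilities remain well behaved — Newton's method falls back to
BFGS when the Hessian is singular.

Matching is greedy 1:1 nearest-neighbour without replacement: the
majority arm is pruned to the minority arm size; treated units are
processed in descending propensity; candidates are controls within a
caliper of 0.25 SD of the **logit** propensity; among candidates, the
smallest Mahalanobis distance over the matching covariates (pooled
covariance, pseudo-inverse for singular cases) wins, ties broken by the
first control in input order — making the procedure deterministic and
permutation-invariant when distances are untied. Balance is reported as
standardized mean differences before/after with pre-matching SD
denominators, the convention that keeps the two columns comparable.
An empty match (no treated unit has a within-caliper candidate) warns and
returns an empty sample rather than raising.

## Total-score and per-symptom inference

ANCOVA: `final ~ baseline + treatment`; F-test on the treatment term;
partial omega squared ω²ₚ = (SS_t − df_t·MS_e)/(SS_t + (N − df_t)·MS_e);
estimated marginal means at the grand-mean baseline with model-based SEs.
The same contrast per item, with Benjamini–Hochberg step-up adjustment
across the 16 tests ("FDR" is taken to mean BH, its default meaning in
applied work; the per-symptom test mirrors the baseline-adjusted
total-score model rather than an unadjusted t-test, so the two analyses
differ only in the outcome). Cohen's d uses the (n−1)-weighted pooled SD
and is computable from group summaries alone; Cramér's V comes from the
chi-square statistic of a contingency table.

## Model-variant comparison

The analysis grid is 12 models: all five change methods × both baselines
on the whole sample, plus RP/RC at the session-2 baseline on the matched
sample (labels `DS1 … RC2, RPX2, RCX2`). Variants are compared by Pearson
correlation of their 16-entry direct vectors and their 120
upper-triangular moderation entries, computed on the raw (zero-heavy)
parameter vectors with no sparsity filtering — the simplest reading of a
"correlation between matrices". A zero-variance vector (a variant that
selected nothing) yields a missing correlation with a warning rather
than a fabricated value.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, so that every
stage is testable without patient-level records:

- **Items**: a 16-dimensional latent Gaussian with a two-block
  correlation (0.40 within depression, 0.45 within anxiety, 0.25 across)
  thresholded at (−1.3, −0.3, 0.6) into {0, 1, 2, 3}, giving right-skewed
  severity marginals (baseline per-item mean ≈ 1.8, matching
  treatment-seeking totals of PHQ-9 ≈ 16, GAD-7 ≈ 13.5).
- **Occasions**: latent AR(1) with autocorrelation 0.7 between
  consecutive occasions plus mean drifts (−0.25 while waiting, −0.55
  during treatment), so regression to the mean between session 1 and 2 —
  the phenomenon that motivates the baseline comparison — is present by
  construction, and final totals land near 9–10.
- **Treatment assignment** is logistic on standardized age, gender,
  employment, medication, impairment and the observed session-1 total
  (default coefficients 0.4/0.3/0/0.2/0.1/0.2), making confounding
  recoverable by refitting the same model.
- **Treatment effects** act on the session-2 → final change: per-item
  latent shifts (default: −0.3 SD on excessive worry, trouble relaxing
  and apprehensive expectation under CBT; +0.3 on failure, i.e. a CfD
  advantage) and arm-specific conditional couplings of the change
  innovation, encoded as off-diagonal precision weights (default 8
  plausible symptom pairs at ~0.3, with two moderation deltas of ±0.2).
  Defaults are moderate rather than the tiny effects reported from
  12k-patient cohorts, because they must be detectable at simulation
  scale (thousands, not tens of thousands).
- **`exact_change_precision`**: with the default AR carry-over the latent
  change distribution has a weak dense background (non-edge partial
  correlations up to ~0.05) on top of the sparse couplings — realistic,
  but ill-posed as a graph-recovery target. This flag adjusts the
  innovation covariance so the latent change has *exactly* the coupling
  graph as its conditional-independence structure, the configuration used
  by recovery checks.
- **Covariates** are drawn loosely matching a routine-care population
  (age ~ N(41, 13), ~31% male, six-category ethnicity, WSAS-like
  impairment tied to latent severity); attendance ~ Poisson(10.5 + 0.5·T)
  with the ≥5-session inclusion filter applied downstream; waiting days
  ~ N(59.9 + 6.5·T, 49).

Not emulated: dropout mechanisms, per-week session trajectories,
therapist effects, item-level missingness patterns, and floor effects
beyond what thresholding produces. Passing recovery tests therefore shows
that the estimator finds structure *of the kind generated here* at
realistic sample sizes — not that real cohorts satisfy these
assumptions, nor that specific published effect magnitudes (which derive
from non-deposited records) are reproduced.

## Problem sizes and determinism

Simulation-based checks run at n_per_arm = 2000 (≈ 4000 patients), with
20 seeded repeats for rate estimates and 500 replicates for the ANCOVA
calibration — sizes at which the measured properties are stable while a
full run stays in the minutes range on one CPU. All randomness flows from
explicit integer seeds; the pipeline fans one run seed into per-stage
seeds via `numpy.random.SeedSequence`, recorded in the run manifest, and
reruns are byte-identical.

## Known limitations

- Nodewise elastic net estimates a conditional Gaussian model on ordinal
  change scores; discretization attenuates couplings (observed partial
  correlations ≈ 0.2 for generating weights of 0.3) and induces small
  systematic dependencies (≲ 0.02) that no sample size removes.
- The matched-sample grid refits residualizing regressions within the
  matched subset; with small matched samples the selection threshold is
  correspondingly larger and weak direct effects drop out — visible in
  the README example.
- Greedy matching is not optimal matching; it approximates the
  minimum-distance assignment and equals it on well-separated data, but
  no global optimality is guaranteed.
- The bootstrap refits the CV selection per resample, which is honest but
  expensive; the default of 1000 resamples is impractical above small
  cohorts on one CPU and the pipeline exposes `n_boot` for that reason.
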