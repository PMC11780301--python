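# Methods

## Scope and data model

`healthgap` analyzes person-level survey tables of adults aged 50+ with
three blocks of columns: demographics and socioeconomic controls, digital
connectivity/use indicators, and raw health-instrument items (see the
JSON column dictionary written next to every cohort CSV). Records under
age 50 are excluded first; records with missing key health variables are
excluded per model (listwise, per dimension). Exclusion counts are
reported against the initial N (the survey-flow convention) and against
each step's own denominator, since the two conventions differ and both
appear in practice.

## Health scoring and orientation

ADL and iADL are 6-item scales, each item 1 (no difficulty) to 4 (cannot
do), summed to 6–24. Cognition is consumed as a precomputed 0–30 MMSE
total; self-rated health is a single 1–5 item. All scores are oriented
so larger = healthier before any inequality computation: ADL/iADL via the
involution x ↦ 30 − x on [6, 24], SRH and cognition via identity. A row
missing any item of a scale is flagged incomplete for that scale only.

## The deprivation index

Per dimension, individual inequality is the Kakwani relative deprivation
RD_i = (1/nμ_Y) Σ_j (y_j − y_i)₊, computed in O(n log n) from the sorted
sample with suffix sums. Conventions:

* **Ties.** "Healthier" means *strictly* greater; equal-health peers do
  not deprive each other. RD is exactly 0 at sample maxima (set
  explicitly, avoiding floating-point residue).
* **Reference population.** RD is computed within the analysis sample of
  one wave and one dimension (after that dimension's listwise deletion),
  because μ_Y and the healthier-than sets are sample-relative.
* **Preconditions.** Finite values, nonempty sample, μ_Y > 0; violations
  raise rather than return NaN.
* **Internal oracle.** mean(RD) equals the Gini coefficient; both are
  computed by independent code paths and the identity is asserted in the
  test suite to 1e−10, with the O(n²) double-sum as a second oracle at
  1e−12.

Each dimension gets its own RD column; no composite across dimensions is
formed, matching the four-outcome reporting layout the pipeline emits.

## Digital-divide indicators

Access = 1 iff any of {broadband, ≥1 smart device, ≥1 other digital
device}. Use = WeChat + Moments + mobile-payment (0–3), defined only when
all three items are observed; the items are structurally unobserved for
respondents without a smart device, and use-level analyses are restricted
to the fully observed subsample. For matching, use is binarized at the
sample median with the deterministic rule *strictly greater than the
median → 1* (ties at the median → 0); the rule is conservative for the
treated group and invariant to monotone relabelings of the score.

## Outcome models

OLS of RD on the exposure plus controls with classical SEs. All
regressors — dummies included — and the outcome are z-scored (ddof = 1),
so reported betas are fully standardized; this convention is applied
uniformly because the tidy output reports standardized coefficients for
every term. Income is winsorized at the 1st/99th percentiles
(configurable) then transformed log10(x + 1), which keeps zero incomes
finite and the covariate on a compressed scale. Education (reference: no
formal education), insurance (reference: other insurance) and region
(reference: eastern) enter as dummies. Rank deficiency raises an error
naming the collinear columns; in subgroup fits a rank-deficient or
undersized level is skipped with a warning instead (a subgroup can
legitimately lack a reference category).

Moderation adds a product of the mean-centered exposure and moderator.
Subgroup splits are sex, age (<60 vs ≥60), hukou, education, region; the
splitting variable is removed from the covariate set. The univariate
screen uses the uncorrected chi-square for categoricals and, for
continuous variables, a two-sample t test when Shapiro–Wilk (on at most
5000 sampled values per group) does not reject normality in either arm at
α = .05, otherwise the Wilcoxon rank-sum.

## Propensity-score matching

Logit propensity on the full control set by maximum likelihood (perfect
separation raises with advice). Matching is greedy 1:1 nearest-neighbor
without replacement, treated processed in descending propensity order,
distance ties to the lowest control index — fully deterministic. No
caliper by default; with one, unmatched treated are dropped and counted.
ATT = mean within-pair outcome difference; SE/p from a paired t test.
Balance is |mean_T − mean_C| / √((var_T + var_C)/2) per covariate, before
matching on the full arms and after on the matched samples, flagged at
the 0.20 (20%) adequacy threshold; propensity support ranges and
Gaussian-KDE summary statistics (Silverman bandwidth, fixed grid) are
emitted as numbers, not figures.

A structural caveat governs when this design can work: 1:1 matching
without replacement needs a control reservoir. With the access exposure
the two arms are nearly equal (2018) or treated are the majority (2020),
so the matched control sample is almost the entire control arm and
balance barely moves. The matched sensitivity experiments therefore use
median-binarized use, whose treated group is a minority (~27%) of the
use-eligible subsample; access-exposure matching still runs in the
pipeline and its balance table reports whatever it achieves.

## Synthetic cohort generator

The generator emulates a two-wave ageing survey with known ground truth:

* **Marginals.** Wave-specific prevalences (sex, marital status,
  education, hukou, insurance, chronic disease, disability,
  intergenerational support, region, broadband ~39% in 2018 vs ~57% in
  2020, smart-device ownership ~10% vs ~36%, use-item rates among
  owners) are calibrated loosely (±5 points) to published wave
  descriptives; age is truncated normal on [50, 110]; log10(income+1) is
  truncated normal (mean ≈ 0.72, SD ≈ 0.34); outpatient visits are
  Poisson clipped to [0, 30].
* **Confounding.** A single standardized index u (education +0.6, age
  −0.4, rural hukou −0.6, log income +0.3, scaled by 0.70) shifts the
  logit of every connectivity indicator and enters latent health, both
  weighted by `confounding_strength` (default 0.5, which yields
  pre-match SMDs of roughly 0.2–0.4 on the confounders — recognizable
  observational confounding).
* **Outcome.** Latent health = conf·u + 0.1·male − 0.4·chronic −
  0.5·disability + τ·D + N(0, 0.8), with D the derived access indicator
  and τ (`treatment_effect_tau`) optionally heterogeneous by a binary
  covariate (`tau_heterogeneity`, e.g. a rural-only effect). Each
  instrument discretizes its own noisy copy (SD 0.8) of the latent
  monotonically: SRH by fixed thresholds, ADL/iADL items by a reflected
  linear map rounded into {1..4}, MMSE by a linear map rounded into
  [0, 30]. Monotonicity guarantees that a larger τ improves every
  oriented score in distribution.
* **Missingness.** Item-level missingness at `missing_rate` per cell on
  SRH, the twelve ADL/iADL items and the MMSE total, independent and
  completely at random; use items are additionally structurally missing
  for non-owners of smart devices.
* **Determinism.** One `numpy` Generator consumed in a fixed order;
  identical configs are byte-identical on disk.

What the generator does **not** emulate: survey weights and sampling
design, household clustering, longitudinal linkage across waves,
informative (non-random) item missingness, joint covariate distributions
beyond the single confounder index, and ordinal measurement error.
Passing tests therefore demonstrate that the estimators recover known
effects under a linear-index, MCAR, single-confounder world — not that
any real-world association is causal.

## Calibrated effect sizes

`calibrate_tau` finds the τ producing a target standardized
exposure–deprivation beta. The mapping τ → beta is smooth, monotone
(positive τ ⇒ negative deprivation beta) but mildly sublinear, so the
root is found by a secant iteration (probe 0.2, two refinements) on one
large common-random-numbers cohort (default n = 80,000, fixed seed);
measured recovery error of the calibrated beta across independent
cohorts is below 0.003.

## Problem sizes and numerical conventions

Simulation-based checks use cohorts of 500–5,000 respondents and 100–200
replicates, with one 80,000-respondent calibration cohort — sizes at
which every Monte-Carlo assertion has comfortable margin while the whole
suite runs in well under a minute per heavy test. Tolerances: 1e−12
against the O(n²) deprivation oracle, 1e−10 for the Gini identity, 1e−8
against the normal-equations OLS oracle; statistical assertions use 3-SE
bands or the replicate fractions stated in the tests. Degenerate inputs
(empty vectors, zero-variance differences, constant moderators, absent
reference categories) raise or warn explicitly rather than propagating
NaN.

## Pipeline

The `run` verb sequences ingest/generate → score → divide → deprivation
→ univariate screen → adjusted models with subgroups → matching, writing
CSV/JSON artifacts and a manifest (stage, rows in/out, timings,
exclusion report). Stage randomness (the synthetic draw, the Shapiro
subsample) derives from the top-level seed via `SeedSequence.spawn` in
stage order; everything downstream of the data is deterministic, and a
rerun with the same config and seed reproduces all artifacts byte for
byte.
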