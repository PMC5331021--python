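# Methods

`actiphase` implements an analysis pipeline for minute-epoch wrist
actigraphy recorded from psychiatric inpatients in an acute bipolar
episode (mania, bipolar depression, or a mixed state): it extracts one
64-minute "active" period from the morning and one from the evening of
each ~22-hour recording, computes six linear and non-linear activity
parameters per period, and classifies subjects by phase of illness with
a canonical discriminant-function analysis (DFA). Because no raw
recordings are publicly deposited for this population, the package also
contains a first-class synthetic-cohort generator calibrated to the
published phase-specific feature distributions.

## Day windows and the active period

Recordings are 1-min epoch activity counts starting mid-day (default
12:41, the reported mean start time) and lasting 22 h. Analysis is
restricted to 06:00–24:00, split into a morning window [06:00, 15:00)
and an evening window [15:00, 24:00); windows are half-open, so 15:00
belongs to the evening only. A 22-h recording that starts mid-day covers
the morning window twice (a partial tail on day 1 and a longer stretch
on day 2); the default `prefer_maximal_coverage` rule takes the instance
with more recorded minutes (ties to the earlier day), which maximizes
the chance that the 64-min search succeeds. `first`/`second` day rules
are available for sensitivity analysis. Gaps in a recording are a hard
error, not imputed.

Within a window, the **active period** is a 64-min contiguous segment —
64 because the spectral analysis needs a power-of-two length — found by
tolerance escalation: at tolerance k = 2 a segment qualifies if it
contains no run of more than k consecutive zero-count minutes; the
window is slid in 1-min steps (from the start of the window for the
morning, from the end for the evening, i.e. the latest-starting
qualifying window) and if no position qualifies, k increases by one.
All start positions are tried at tolerance k before any is tried at
k + 1, and tolerance k = 64 always qualifies, so the search terminates.
The search is verified against brute-force enumeration over all
(tolerance, start) pairs.

## Activity parameters

For a 64-min segment x₁…x₆₄ (counts/min):

| parameter | definition | captures |
|---|---|---|
| `mean_cpm` | arithmetic mean | overall activity level |
| `sd_pct` | 100·s/mean, s the sample SD (n−1) | intra-individual fluctuation |
| `rmssd_pct` | 100·RMSSD/mean, RMSSD = √(mean of (x_{t+1}−x_t)²) | minute-to-minute variability |
| `autocorr_lag1` | lag-1 autocovariance ÷ variance (correlogram convention) | persistence/regularity |
| `sampen` | sample entropy, m = 2, r = 0.2, on the standardized series | complexity/irregularity |
| `fourier_ratio` | spectral variance in periods [2, 8) min ÷ periods [8, 64] min | fast vs slow variation |

Conventions, fixed once and used everywhere: sample statistics use the
n−1 denominator (including the "sample mean 0, sample variance 1"
standardization before entropy and spectral analysis). The correlogram
autocorrelation estimator is the default because it is what mainstream
statistics packages produce; a Pearson-on-pairs variant is available via
`method="pairs"`. Sample entropy follows Richman–Moorman exactly: the
N−m = 62 overlapping templates, self-matches excluded, −ln(A/B); when
A = 0 or B = 0 the value is flagged undefined and the subject excluded
with a logged reason — no substitution rule is applied. The spectrum is
the plain periodogram of the standardized segment (mean removal only, no
taper); the variance in bin k (period 64/k min) is 2|X_k|²/n² for
0 < k < 32 and |X_k|²/n² at Nyquist, so bins k = 1…32 partition the
variance exactly (Parseval closure is asserted to 1e-9 in tests). The
8-min band edge is assigned to the low band so the bands partition the
non-DC spectrum; the Nyquist bin (2 min) belongs to the high band. The
ratio is flagged undefined when the low band carries only numerical
round-off.

## Discriminant analysis

Predictors are the 12 features (6 parameters × morning/evening),
residualized by OLS on age and gender and standardized ("standardized
residual scores", mean 0, SD 1, exactly orthogonal to the covariates).
A one-way MANOVA (Wilks' Λ with Rao's F approximation; exact for two
groups) screens for an overall group difference.

The DFA solves the generalized eigenproblem B·a = λ·W·a (between- vs
pooled within-group scatter); with g = 3 groups and p = 12 predictors
there are min(g−1, p) = 2 discriminant functions. Conventions follow
the classical SPSS presentation so outputs are comparable to published
tables:

- coefficients scaled so discriminant scores have pooled within-group
  variance 1 and are centred at the grand mean (the group-size-weighted
  centroid mean is exactly 0);
- canonical correlation rᵢ = √(λᵢ/(1+λᵢ)); Wilks Λ_k = Π_{i≥k} 1/(1+λᵢ);
  Bartlett χ²_k = −(N−1−(p+g)/2)·ln Λ_k with df (p−k+1)(g−k);
- the structure matrix holds pooled within-group correlations between
  each predictor and each function; reports mask |r| < 0.3 (a
  conventional interpretability floor at this sample size) while the
  full matrix is always retained;
- signs are fixed so each function's largest-magnitude structure
  loading is positive (eigenvector signs are otherwise arbitrary).

Classification uses Fisher linear classification functions
(pooled-covariance, prior-adjusted; equivalent to smallest prior-adjusted
Mahalanobis distance). Priors default to group proportions with an
`equal` switch, since the original prior setting is not recoverable; tie
scores break deterministically to the earliest group in sorted label
order. Classification agreement with an independent pooled-covariance
implementation (scikit-learn's LDA) is asserted on 50 seeded datasets.

Leave-one-out cross-validation refits the classification rule on the
N−1 retained cases for every fold (proportional priors are recomputed
per fold); singular folds leave their case counted as unclassifiable,
never silently dropped. The stratified case bootstrap (default 1000
replicates) resamples within group, refits the full model per replicate,
drops and counts singular replicates, and reports percentile 95%
intervals for eigenvalues, canonical correlations and apparent accuracy.
On pure-noise predictors the mean LOOCV accuracy sits at the
prior-implied chance rate Σ p_g² with the small pessimistic offset
characteristic of leave-one-out (each held-out case's own group loses a
member); the null-calibration test asserts no optimism and a bounded
offset.

Confusion tables carry per-group and overall accuracy and a Pearson χ²
of the g×g contingency table (expected counts from the margins,
df = (g−1)²). No multiple-testing correction is applied anywhere; all
p-values are reported raw. The default significance threshold is 0.05.

## Synthetic cohort generator

The generator's defaults are the study conditions: 34 subjects split
12/16/6 (bipolar depression / mania / mixed) by largest-remainder
rounding, 22-h recordings from 12:41, gender Bernoulli(0.56 female),
ages normal per phase with the published group means and SDs
back-computed from the published t-based 95% CIs (truncated at 18, the
inclusion criterion). Each subject consumes one spawned random stream,
so adding knobs or subjects never perturbs other subjects and identical
config + seed is bit-identical.

A recording is assembled from three regimes: a low zero-inflated night
(00:00–06:00) and stationary morning and evening day regimes. Within a
day regime, counts are X_t = μ·ℓ·((1−β) + β·L_t), with L_t a mean-1
gamma marginal obtained by quantile transform of a standard Gaussian
latent G_t that mixes an AR(1) with white noise. Each knob maps to one
target feature:

- μ — the phase/period target mean (counts/min);
- gamma shape 1/CV_L² — set analytically from the target SD%;
- latent lag-1 correlation — solved through the Hermite expansion of
  the quantile transform (which maps latent to observed
  autocorrelations), from the target lag-1 autocorrelation plus the
  (1+3ρ)/n small-sample bias adjustment of the 64-point correlogram;
- AR coefficient φ — solved by bisection so the exact finite-n expected
  periodogram of the process ACF matches the target band ratio. The
  band ratio is U-shaped in φ (as φ→1 the within-window process
  degenerates to constant-plus-white, whose demeaned spectrum is flat),
  so the solver brackets only the decreasing branch up to the interior
  minimum;
- β ∈ (0, 1] ("burstiness") — reshapes the marginal at fixed CV (small
  β = steady base with occasional bursts, whose standardized segments
  are more self-similar) and serves as the sample-entropy knob.

RMSSD needs no knob: the published RMSSD values are jointly consistent
with SD% and lag-1 autocorrelation (RMSSD ≈ SD·√(2(1−r₁)) holds within
the published CIs for all six phase-periods), so it emerges from the
process.

64-point sample statistics of skewed, autocorrelated counts are biased
relative to population values (sample-SD shrinkage, correlogram
attenuation, the Jensen gap of the per-segment band ratio), so each
phase-period carries four small frozen correction constants (`cv_gain`,
`r1_shift`, `fourier_gain`, `burstiness`) fitted once by the iterative
Monte-Carlo routine `calibrate_profiles`, which pushes the mean
*extracted* features — through the real slice → active-period → feature
pipeline — onto the targets (150 replicates/phase, 8 rounds, damping
0.6). The shipped defaults reproduce all 36 phase-period feature means
inside the published 95% CIs at 200 replicates per phase; that check is
a standing acceptance test.

Between-subject spread comes from a subject-level lognormal multiplier
on μ (CV 0.45, shared by morning and evening so levels co-vary within
subject) plus small mean-preserving jitters on the CV, lag-1 and
spectral targets; these were chosen so the simulated group-mean CIs at
n = 12/16/6 are of the same order as the published ones. The published
CIs are model-adjusted (age/gender-controlled); the generator treats
them as plain group CIs, the only reading that supports calibration.

What the generator does **not** emulate: sleep staging and architecture,
naps, device non-wear (beyond optional zero-run injection), medication
effects, and any within-day nonstationarity beyond the three-regime
envelope. Passing tests therefore demonstrate that the *pipeline and
statistics* behave correctly on data with the published first- and
second-order feature structure — not that the generator reproduces every
property of real inpatient actigraphy. In particular the classification
accuracies obtained on synthetic cohorts characterize the method under
the calibrated separations, not the clinical separability of real
patients.

## Numerical choices and degenerate inputs

- Segment length must be a power of two (validated); the zero-run
  tolerance starts at 2.
- Counts are integers ≥ 0; a window shorter than 64 min is an
  `InsufficientDataError` carrying subject and window.
- A constant segment has undefined autocorrelation, entropy and band
  ratio; such subjects are excluded with a logged reason.
- The degenerate noise-free profile (SD% = 0) yields a constant series,
  used as a generator smoke test.
- Generalized eigenproblems are solved with the symmetric-definite
  solver (`scipy.linalg.eigh(B, W)`), guaranteeing real spectra;
  singular scatter raises `SingularityError` with guidance rather than
  producing garbage. N ≤ p + g − 1 is rejected up front.
- Hermite expansion: 40 terms, 240 Gauss–Hermite nodes; quantile
  transforms clamp the normal CDF away from 1 to avoid infinities. The
  residual approximation error is absorbed by the calibration
  constants.

## Problem sizes in tests and the acceptance script

The standing suite uses 200 replicate subjects per phase for the
calibration check, 1000 seeded series for the active-period oracle,
100 segments for the entropy oracle, 50 datasets for the discriminant
oracle, and 500 replicates for the LOOCV null calibration; the
end-to-end run uses the study's n = 34 with a 1000-replicate bootstrap.
These sizes give Monte-Carlo standard errors comfortably inside the
asserted bands while keeping a full run in well under a minute for the
pipeline and a few tens of seconds for the whole acceptance script.

## Known limitations

- The published Bartlett χ² values are not reproducible from the
  published eigenvalues with the textbook multiplier at N = 34, p = 12,
  g = 3; the package implements the textbook form and makes no attempt
  to reverse-engineer the original run's predictor set.
- The original cross-validated accuracy (55%) and MANOVA F depend on
  the undeposited patient data; synthetic-cohort analogues are reported
  but are not point reproductions.
- Sample entropy on 64 points is noisy and occasionally undefined
  (no length-3 template matches); exclusion, not imputation, is the
  policy, matching the reporting of undefined values upstream.
- The generator's calibration targets group *means*; higher moments and
  cross-feature correlations within subject are emergent, not
  controlled.
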