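# Methods

`actidx` implements an actigraphy analysis pipeline for differential
dementia diagnosis: epoch-level activity-category/intensity series from
body-worn sensors are summarized into per-period activity and circadian
features, and a feature-selecting logistic classifier is evaluated in
nested leave-one-out cross-validation with exact-binomial performance
intervals. Because no real cohort ships with the package, a synthetic
generator provides cohorts with configurable group-level structure; this
note records the model, the defaults and the reasoning behind the open
design choices.

## Data model and windowing

Input is a per-subject sequence of 5-second epochs, each carrying one of
nine activity categories (upright standing, sporadic walking, walking,
running, moderate intensity, lying rest, lying movement, sitting,
cycling) and a unitless intensity count. Epochs are aggregated into
clock-aligned 15-minute windows (window starts at multiples of the
window length past local midnight; the trailing partial window is
dropped). Per window the pipeline stores the time fraction in each
category (relative to the full window, so the fractions plus the
non-wear fraction sum to one exactly), the summed intensity count, the
wear fraction, and two derived event signals: sit-to-stand transitions
(sitting epoch followed by an upright-category epoch on the adjacent
grid slot) and a step count from nominal cadences (sporadic walking
0.8, walking 1.7, moderate intensity 2.0, running 2.8 steps/s). Real
sensor systems report steps and posture transitions directly; the
cadence constants only matter for the synthetic route and are package
choices.

Analysis periods are the full day anchored at 22:00 (96 windows), night
00:00–06:00 (24 windows) and daytime 09:00–21:00 (48 windows), with
window membership decided by window start time. Epochs absent from the
export are non-wear; a full period whose mean wear fraction falls below
`min_wear` (default 0.8, counting absent windows as zero wear) is
excluded, which prevents fragmentation indices from being driven by
gaps. When two sensor streams exist (thigh and chest), the thigh stream
drives the default feature set; chest series are accepted and stored.
Local naive clock time is assumed throughout (no time-zone or DST
arithmetic).

## Features

For each valid day, each period and each category the pipeline computes
the mean time fraction, the percentage of windows with strictly more
than 5%, 10% and 25% of time in the category, and the intra-daily
variability (IV) of the fraction sequence

    IV = n * sum_{i=2..n} (x_i - x_{i-1})^2
         / ((n-1) * sum_i (x_i - mean(x))^2),

which is ≈2 for white noise and small for smooth profiles; a constant
sequence has an undefined IV, propagated as missing rather than a
division error. The intensity-count signal adds, per period, the mean,
the mean over windows whose modal category is sitting, and the IV; on
the full period only it adds M10 and L5 — the mean count over the most
active contiguous 10 h and least active contiguous 5 h, blocks stepped
one window at a time without wrapping, ties to the earliest start — with
their onset clock times and the relative amplitude
RA = (M10−L5)/(M10+L5). M10/L5 are restricted to the full period because
the night period is shorter than a 10-hour block and a 12-hour daytime
block would change the indices' meaning. The two event signals get a
mean and an IV per period.

This default registry yields 161 per-day features; summarizing each by
its across-day average and unbiased (n−1) variance gives 322 per-subject
features. The registry is explicit and configurable (categories,
periods, count/event signals can be included or excluded) and the 2×
summary identity is asserted in tests; the exact enumeration that would
produce some other fixed count is not derivable from the feature
families alone, so the registry definition is shipped alongside every
feature table as a JSON sidecar. Subjects need at least two valid days
for variances; with fewer they are flagged and dropped from
classification by default. IV is applied to window-level time-fraction
sequences for categories and to the window count sums for intensity.

## Synthetic cohorts

The generator emits category labels and counts directly (real systems
derive them from raw accelerometry with proprietary classifiers, which
is out of scope). Per subject, the expected count of the window at clock
hour h is a clipped cosinor plus an optional late-afternoon Gaussian
bump; a binary rest/active state has its baseline at drive > mesor and
flips independently per window with probability `frag_rate`; expected
counts are the rest level (mesor − amplitude) in rest windows and the
cosinor drive in active windows, so fragmentation creates count-level
jumps (IV increases monotonically with `frag_rate`, verified by
simulation). Nighttime wake windows are injected at `night_wake_rate`
per night and carry a count boost of half the mesor, elevating L5 for
fragmented sleepers. Window counts get multiplicative log-normal noise
(log-SD 0.3) and are distributed over the 180 epochs of the window
proportionally to per-category intensity weights via Poisson draws, so
category composition and counts stay consistent. Window categories come
from state-conditional mixes, with walking emitted in geometric bouts
(mean `walk_bout_mean` windows) and epochs mixing 75% window-dominant
category with 25% redraws.

Between-subject heterogeneity is essential for realism: subjects draw a
log-normal activity-level multiplier (CV 0.25), a Dirichlet-jittered
category mix (concentration 60), a gamma-distributed night-wake rate
(shape 4), jittered fragmentation (log-SD 0.3), phase (SD 0.75 h) and
walking-bout length. Without it, group profiles separate at ~8 pooled
SDs and any classifier is trivially perfect; with it, per-group feature
CVs land in the 0.2–0.8 range reported for real cohorts and the
strongest planted group effects are ~1.5–3 pooled SDs.

The bundled preset encodes only the direction and coarse magnitude of
published group-level contrasts: overall intensity healthy controls >
Alzheimer's disease > Lewy-body dementia > vascular groups (39.1, 31.7,
29.1, 21.4, 19.5 counts/min as generative targets), elevated
least-active-5-hour counts and fragmentation in the Lewy-body and
vascular groups, a late-afternoon activity bump only in controls, and
demographic covariates per group. Reported per-window M10/L5 means are
consistent with the per-minute overall levels via overall ≈
(M10+L5)/2/15, which fixes the scale convention: preset levels are
counts/minute × 15 per window. Because the expected window count of the
state-gated cosinor is E = rest + amplitude·mean[(1+cos)·P(active)] (+
bump and wake terms), the preset inverts that expectation on the
discrete window grid to place mesor and amplitude on the requested
overall level with the trough pinned at the L5 target. Default group
sizes are the study-scale 70/29/8/15/48. The preset is not a fit to any
recorded data; passing recovery tests on it shows the pipeline detects
structure of this kind and magnitude, not that it would reach the same
performance on real cohorts (no wear artifacts, no behavioral
covariance between features beyond the planted one, no label noise).

Subject seeds derive from the master seed via `SeedSequence(master,
spawn_key=(index,))`, so cohorts are byte-reproducible and insensitive
to generation order.

## Classifier

Each binary task maps diagnoses to two sides (mixed-pathology and pure
vascular dysfunction merge into one CVD class; all patient groups merge
into "disease" against controls). For every held-out subject the
remaining subjects are standardized (their own mean/SD), ranked by
greedy mRMR (mutual-information difference scheme, features discretized
into three equal-frequency bins, k = 30 retained, exact ties to the
lower column index), and searched by sequential forward selection:
a candidate enters only if it improves inner leave-one-out accuracy of
the unregularized logistic fit by at least `sfs_min_gain = 3` correctly
classified subjects (cap 10 features). Requiring a multi-subject gain
matters: a one-subject improvement is within the noise of the
leave-one-out estimate itself, and admitting it lets noise features
accumulate and pushes out-of-fold accuracy on null data systematically
below chance. With the empty selection the fold emits probability 0.5 —
the training prevalence would anti-correlate with the held-out label by
fold construction.

Logistic fits are unregularized maximum likelihood via Newton-Raphson;
a 1e-8 Hessian ridge gives numerical solvability and an L∞ coefficient
cap of 15 (standardized scale) keeps separated fits finite and flagged.
Inner leave-one-out probabilities are obtained by a batched Newton
iteration that solves all n leave-one-out problems simultaneously
(Hessians assembled with one matrix product over the precomputed
outer-product design; per-problem convergence at 1e-6), which is what
makes nested LOOCV with an inner LOO criterion affordable at cohort
scale on one core. Agreement of the solver with scikit-learn at
negligible regularization and of the batched path with explicit per-fold
refits is under test.

Performance is reported at the default 0.5 threshold and at a threshold
optimized on the pooled out-of-fold probabilities as the ROC point
closest to (0,1) (candidates are midpoints of sorted distinct
probabilities plus the endpoints; distance ties go to the lower
threshold). Sensitivity, specificity, accuracy and precision carry 95%
Clopper–Pearson intervals on their own denominators; F1 is the harmonic
mean of precision and sensitivity and, not being a simple binomial
proportion, is reported without an exact interval. A single-feature
comparator (leave-one-out logistic on the average 24-hour intensity
count; a flag switches to the daytime mean) and a feature-importance
table (mean absolute standardized coefficient across folds, unselected
folds counting zero) accompany every result.

## Group statistics and confounder probe

Feature tables are compared across groups with tie-corrected
Kruskal–Wallis tests (chi-square approximation; all-identical input is
degenerate and reported as H = 0, p = 1; no multiple-testing correction
is applied across the feature screen). Group-average 24-hour intensity
curves smooth each subject's mean clock profile with a circular 1-hour
(four-window, quarter-weight) moving average — which conserves the daily
mean exactly — and carry an across-subject standard-error band.
Actograms render one row per recording day colored by modal window
category with fixed category colors. The confounder probe regresses
out-of-fold probabilities on age, sex and the four medication flags
(OLS on the identity scale by default, switchable to a logit-transformed
response since the appropriate link is an open choice), dropping
constant covariates with a warning.

## Numerical and degenerate-input conventions

Undefined statistics (IV of constants, RA at M10 = L5 = 0, precision
with no predicted positives, variance with a single day) are missing
values, never exceptions, and missingness propagates to the subject
summary where averages skip missing days. Feature columns with any
missing value or zero variance are dropped before classification.
M10/L5 tolerate up to 10% missing windows by ignoring them inside block
means. All randomness flows from explicit seeds; reruns of the pipeline
with an identical configuration are byte-identical for the deterministic
stages.

## Problem sizes

The default test and acceptance workloads use: the study-scale cohort
(170 subjects × 7 days at 15-minute resolution) for the end-to-end run;
50 subjects per group × 5 seeds for the recovery experiment; 40 subjects
× 100 features × 5 seeds for the selection-bias control; 2000 replicates
for interval coverage and test-size checks. These sizes make every
stochastic check tight enough to be meaningful while keeping a full run
on a single core in the minutes range.

## Known limitations

The generator does not emulate raw accelerometry, sleep stages, REM
behavior disorder, wear artifacts beyond missing epochs, or
inter-feature behavioral covariance beyond the planted circadian/
composition structure. The classifier is logistic-only by design; no
external-cohort validation is possible from synthetic data, and
performance numbers on the preset characterize the pipeline, not any
clinical population.
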