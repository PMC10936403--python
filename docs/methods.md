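# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of the `ftss` package in enough detail to re-derive every
decision the code makes.

## Signal model and preprocessing

A recording is a time-stamped tri-axial acceleration (m/s²) and angular
velocity (deg/s) series at a nominal 102.4 Hz.  Timestamps must be strictly
increasing with a median interval within ±5% of nominal; beyond that the
recording is rejected rather than resampled — the device samples at a fixed
rate, and silent resampling would invent data.

Preprocessing is a fixed chain, asserted in order:

1. **Calibration** — the Ferraris sensor model
   `corrected = M · (raw − offset)` applied independently to accelerometer
   and gyroscope.  Identity matrix + zero offset is the neutral
   calibration; singular matrices are rejected.
2. **Band-pass** — Butterworth 0.01–5 Hz.  The filter order is a design
   choice: 2nd order applied forward–backward (`sosfiltfilt`), i.e.
   zero-phase with an effective 4th-order magnitude.  Zero phase matters
   because segmentation reads event *times* off the filtered signal; a
   causal filter would bias every fiducial late.  The measured response of
   the effective filter has gain ≥ 0.95 at 1 Hz and ≤ 0.1 at 20 Hz, with
   exact zero at DC.
3. **Settling trim** — the first 1.0 s is discarded and time re-referenced
   to zero; trials shorter than the trim are rejected.

Signal-validity gating (spikes, orientation, dropouts) is applied to the
*unfiltered* signal in the command-line pipeline: a single-sample spike is
trivially visible there, whereas the 5 Hz low-pass smears it into a small
smooth bump that no longer witnesses the artifact.  The checks themselves:

* **Spike** — residual against a 5-sample median filter; samples whose
  residual exceeds `max(10 × MAD(residual), 5% of signal range)` are
  counted as spikes.  The amplitude floor is needed because genuine FTSS
  movement is smooth at 102.4 Hz: the residual MAD of a clean trial is
  near zero and a pure MAD rule would flag everything.
* **Orientation** — skewness of the primary channel must be positive for
  torso Z (brief large stand/sit bursts dominate) and negative for thigh Y
  (deep mid-stand troughs dominate).  An upside-down or swapped sensor
  flips the sign.
* **Dropout** — any inter-sample gap longer than 3 nominal intervals.

## Segmentation

**Torso.**  Thresholds adapt to the trial: positive peaks of αz above
`0.4·αz_max` and negative peaks below `0.5·αz_min`.  Peak extraction takes
each contiguous supra-threshold region and walks from the threshold
crossing to the sample where the derivative changes sign — i.e. the region
extremum, earliest sample on ties.  A 0.5 s refractory period between
same-sign peaks (a physiological lower bound on an SSS phase) suppresses
noise doublets, keeping the larger peak.  Alternation is enforced by
keeping, between each adjacent pair of positive peaks, only the deepest
negative peak; that trough is the cycle's mid-stand, the preceding positive
peak its stand-start, the following one its sit-end.  A positive peak may
serve as sit-end of one cycle and stand-start of the next.  Because both
thresholds are fractions of the trial's own extremes, detection is
invariant to rescaling the whole trace and equivariant under time shifts.

**Thigh.**  The global minimum αy_min gates acceptance: local minima below
`0.8·αy_min` are successful mid-stands; weaker dips — e.g. an aborted
half-rise — are rejected.  Stand-start and sit-end are the nearest positive
flank peaks (above `0.2·|αy_min|`) enclosing each trough.  This flank-peak
definition is a deliberate design choice: after band-passing, the femoral
signal is near zero-mean, so an "|αy| falls below 10%" onset rule is
crossed mid-flank between the seat-off deflection and the trough rather
than at movement onset.  The positive seat-off/seat-contact deflections are
the robust, physically meaningful movement boundaries.

Degenerate inputs (all-zero signal, no negative trough, no alternating
structure) raise a segmentation error rather than returning empty output.

## Feature roster

Rosters are frozen (`roster_version = "reconstructed-v1"`): exactly 38
torso and 20 thigh features, reconstructed from the feature families
(timing, fiducial amplitudes, sway RMS, jerk, spectral entropy) under those
fixed counts.

* **Timing (11)** — total time (first stand-start to last sit-end),
  cycle count, and mean/SD/CoV of SSS, rise, and descent durations.
  SD uses the n−1 convention and is 0 by definition for a single cycle;
  a CoV whose mean is below 1e-9 raises a degenerate-input error rather
  than dividing silently.
* **Fiducial amplitudes (12 torso / 8 thigh)** — the primary acceleration
  channel and the pitch angular-velocity channel, linearly interpolated at
  each fiducial time, summarized as mean and SD across cycles.  Torso uses
  all three fiducials; thigh uses stand-start and mid-stand.  The pitch
  axis is chosen per trial as the gyro axis of maximal variance in the
  active window (robust to mounting variation) and recorded in the
  feature vector's metadata.
* **Sway and smoothness (6 + 6, torso only)** — per-axis RMS of
  acceleration and angular velocity, and of their central-difference
  derivatives (jerk, m/s³; angular acceleration, deg/s²), over the active
  window.  A thigh-mounted sensor cannot meaningfully measure upper-body
  sway, so these are refused for thigh recordings.
* **Spectral entropy (3 torso / 1 thigh)** — Shannon entropy of the
  normalized periodogram (DC bin excluded, since band-passed signals carry
  none), divided by log of the number of bins so the result lies in
  [0, 1].  Computed per acceleration axis over the active window; requires
  ≥ 64 samples and a non-constant signal.

The analysis window for sway/entropy features is first stand-start to last
sit-end — quiet sitting before and after the task is excluded because
within-task sway is the target construct.

## Exploratory statistics

Features are averaged per subject across trials *before* any testing, so
each subject contributes one observation.  Spearman ρ (with p) against MMSE
and BBS; Wilcoxon rank-sum for faller vs non-faller; chi-square test of
proportions (no continuity correction) for categorical differences between
the home and clinic arms.  Constant features are flagged `constant` with NA
statistics instead of propagating NaN.  No multiple-comparison correction
is applied.

**ICC(2,k)** is computed from the two-way ANOVA mean squares (rows =
subjects, columns = trials): `(MS_R − MS_E) / (MS_R + (MS_C − MS_E)/n)` —
two-way random effects, absolute agreement, average measures.  Absolute
agreement was chosen over consistency because intra-session reliability
should penalize systematic trial-to-trial drift.  The 95% CI uses the
F-distribution method for the single-measure coefficient followed by the
Spearman–Brown step-up; the implementation is cross-checked in the tests
against pingouin's independent implementation to 1e-10.  Bands: excellent
> 0.9, good > 0.75, moderate [0.5, 0.75], else poor — strictly greater at
the upper cut-points, and a degenerate matrix (no between-subject
variance) reports icc ≤ 0, band poor.

**Outcome labels** — faller: more than one fall in the previous 12 months
or any injurious fall (the injurious criterion requires at least one
fall); cognitive impairment: MMSE < 27; balance impairment: BBS < 53.

## Classification pipeline

Design matrix: one row per subject (first trial only, matching a
single-assessment use case), roster features plus age, sex, height, weight.
Sex-stratified matrices drop the constant sex column.  Pairwise interaction
columns (canonical `A:B` names, A before B lexicographically) are built
over a configurable candidate set, by default demographics + total time —
the full pairwise closure over all 40+ candidates would swamp the greedy
search with correlated columns.  Continuous columns are z-scored with
training-fold statistics only; constant columns are dropped with a warning.

The classifier is logistic regression fit by Newton iteration with a 1e-6
ridge on the slopes — numerically the MLE on non-separated data, and a
finite, stable fit under complete separation.  Sequential forward selection
runs inside each of 10 stratified outer folds: starting from the forced set
({total time}), each step adds the candidate maximizing 5-fold inner
cross-validated accuracy on the training fold, stopping when the best
improvement is below 0.5 percentage points or 10 features are reached.
Held-out subjects are classified at probability 0.5 (no operating-point
tuning), and outer-fold predictions are pooled into a single confusion
matrix; metrics with a zero denominator are reported as not-applicable
rather than NaN.  Sex-stratified results can be averaged unweighted
("mean of sexes").  Fold assignment is a pure function of subject order
and seed.

The no-leakage property is asserted two ways: perturbing a held-out subject
provably cannot change the features selected on its fold (targeted test),
and SFS on permuted labels stays at chance accuracy (50% ± a few points
over 20 repeats).

## Regression pipeline

MMSE (0–30) and BBS (0–56) are count-valued with hard ceilings, so the
estimator is Poisson regression with a log link.  Model selection uses the
elastic net at mixing parameter α = 0.1 (mostly ridge with enough ℓ1 to
produce sparsity), fixed a priori.  Per outer fold the penalty path
(25 log-spaced strengths from just above the first-entry point down by
three decades, warm-started) is fit on 75% of the training subjects and
scored by Poisson deviance on the held-back 25%; among penalties whose
active set size lies in the a priori bounds [3, 20] the deviance minimizer
wins (nearest-size model with a logged warning if none qualifies).  The
forced total-time column is excluded from the penalty, which is the only
mechanism that actually guarantees its inclusion.  The winning active set
is then refit by unpenalized maximum likelihood on the full training fold
(a "relaxed" elastic net) before predicting held-out subjects — selection
and shrinkage are thereby decoupled, and reported coefficients are
unbiased at the fold's sample size.  Pooled out-of-fold predictions give
R², RMSE (score points), Spearman ρ; the median active-set size across
folds is the reported model size.  The path implementation reduces to the
unpenalized Poisson MLE as the penalty goes to zero (tested to 1e-4), and
pure ridge (α = 0) zeroes no coefficients.

## Synthetic data

The generator is the package's study population; its defaults are fixed
and the tests run against them.

**Trial level.**  Each cycle is scheduled as stand-start → mid-stand (at a
rise fraction 0.45 of the cycle) → sit-end, with cycle durations
N(2.2, 0.25²) s clipped to [1.2, 4.0] and inter-cycle pauses
N(0.8, 0.15²) s clipped to [0.55, 1.5]; 2.5 s of quiet sitting pad each
end (so the 1 s settling trim never eats movement).  Pulses are Gaussian —
smooth and essentially band-limited within 0.01–5 Hz:

* torso Z: positive bursts of 2.0 m/s² (±8% per-cycle jitter, width
  0.07·duration) at stand-start and sit-end, a −1.5 m/s² trough (width
  0.187·duration) at mid-stand.  The widths make positive and negative
  areas cancel, so each cycle is near zero-mean — necessary because the
  0.01 Hz high-pass removes DC, and a non-zero-mean pulse train would have
  its baseline shifted and trough depths redistributed.  The cube-weighted
  third moment stays positive, preserving the positive skewness a
  correctly mounted torso sensor shows.
* thigh Y: a −3.0 m/s² asymmetric trough (±3% jitter — trough-depth
  consistency is precisely what the 0.8 acceptance gate relies on)
  spanning rise and descent, plus positive seat-off/seat-contact lobes
  (0.45 of trough amplitude, width 0.14·duration).  Lobe centers are
  solved numerically so the *rendered* local maxima land exactly on the
  scheduled stand-start/sit-end — otherwise the trough's gradient drags
  the peaks outward by ~0.15 s and ground truth would not mark the
  rendered morphology.
* gyro pitch: a scaled derivative of the primary channel (8 deg/s per
  m/s³) plus noise; remaining channels carry low-level sway noise only.

Sway noise is white noise band-passed to 0.1–3 Hz at a configurable RMS
(default 0.05 m/s²).  Optional artifacts: a single-sample spike, a
timestamp dropout window, or an aborted half-amplitude rise in a pause.
With zero noise the torso detector recovers every fiducial within one
sample; with defaults, 100 trials per sensor (3–8 cycles, mean durations
1.5–3.5 s) segment with 100% cycle-count recovery and sub-0.05 s median
timing error.  The robustness suite sweeps sway amplitude (≈3×RMS) up to
25% of the 2 m/s² movement peak — the same absolute levels for both
sensors, since sway is a property of the subject, not of each channel —
and requires ≥ 95% cycle-count recovery.  At RMS levels approaching 25% of
the *thigh trough depth* the paper's own 0.8 gate is mathematically
margin-free, so per-channel noise scaling is not a meaningful target.

**Cohort level.**  Demographics: age U(60, 90); sex by a configurable
ratio; height/weight by sex-specific normals.  Subject kinematics (cycle
duration mean/SD, pause, sway RMS) drift mildly with age.  Outcomes are
generated from the subjects' *true* scheduled characteristics (total time,
sway, cycle-duration SD), z-scored across the cohort: MMSE ~ min(30,
Poisson(exp(log 28 + η))), BBS ~ min(56, Poisson(exp(log 52.9 + η))),
faller ~ Bernoulli(σ(logit 0.48 + η)), with default coefficient vectors
small and negative on total time (slower subjects score worse, fall more).
Falls counts and injurious-fall flags are drawn consistently with the
faller definition.  The first 40 subjects form the "home" arm, the rest
"clinic", mirroring a two-sub-study pooled design.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: true biomechanical pulse shapes (real stand-up
accelerations are asymmetric and multi-modal), gravity leakage through
imperfect calibration, orientation drift, overdispersed or
non-count-generated clinical scores (real MMSE at a mean of 28 with SD 2
is far less dispersed than a ceiling-clipped Poisson), correlated
measurement error across trials, and missing data.  Segmentation accuracy
and model-recovery results on this generator are upper bounds on
real-world performance.

**Feature-level generators** (`make_classification_problem`,
`make_poisson_problem`) draw standard-normal design matrices with named
coefficient vectors for validating the learning pipelines in isolation;
the first column is named `total_time` so the forced-inclusion constraint
is exercised.

## Problem sizes and runtimes

The test suite and acceptance script use: 100 simulated trials per sensor
for segmentation recovery; 100 trials for the noise sweep; 50 random
matrices for the ICC oracle; n = 168 subjects × 40 candidates × 20 repeats
for the permuted-label check; n = 400 × 40 for classification signal
recovery; n = 1000 × 40 with 3 true coefficients for elastic-net recovery;
and a 168-subject, 3-trial, two-sensor cohort for the end-to-end
determinism run.  The full suite completes in under ten minutes on one
CPU; the acceptance script in about two.

## Known limitations

* The thigh stand-start/sit-end fiducials are defined by flank peaks; on
  signals without clear seat-off deflections (very slow rises) the cycle
  boundaries degrade to neighboring-cycle lobes, which the timing-error
  distribution's tail reflects.
* ICC confidence intervals assume balanced, complete data; subjects with
  missing trials are dropped (and counted), not imputed.
* The SFS inner criterion (accuracy) is noisy at small fold sizes; the
  0.5-point stopping rule plus the 10-feature cap bounds, but does not
  eliminate, overfitting of the selection path itself.
* Elastic-net size bounds are enforced on the inner-validation path; in
  pathological folds no penalty satisfies them and the nearest-size model
  is used with a warning.
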