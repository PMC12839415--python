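# Methods

This note documents the models, parameter choices, and known limitations of
the `ocatscreen` pipeline: what the synthetic cohorts emulate, how gaze is
turned into the 31 screening features, how the classifiers are trained and
scored, and which design decisions were genuinely open.

## 1. The screening problem

Participants complete a short tablet task (the OCAT): sequences of three
numbers appear one at a time at different screen positions and are mentally
summed; a click advances to the next number.  Position 1/2/3 within a
sequence carries low/medium/high working-memory load.  Gaze is recorded at
120 Hz on a 1920×1080, 14″ screen viewed at 60 cm.  The screening label is
derived from the Mattis Dementia Rating Scale (DRS): scores ≥ 140 are
cognitively normal (CN), scores < 140 are "possible MCI" (PMCI).  The
pipeline trains classifiers to predict that label from task-derived
features — a deliberately imbalanced problem (prevalence ≈ 0.19 at the
default 166 CN / 40 PMCI composition).

## 2. Synthetic cohorts

No public gaze corpus exists for this task, so the generator is a forward
model of the signal the analysis assumes.  What it emulates:

* **Task structure.** Scripts of `n_sequences` × 3 stimuli (default 3
  sequences ≈ 25 s of task; the number is configurable).  Consecutive
  targets cycle through the horizontal/vertical/diagonal planes (angle
  jitter ±15° stays inside the ±22.5° plane bins), with 300–600 px steps
  and a 150 px screen margin.  The next onset coincides with the previous
  click, so per-position response times sum exactly to the total test time.
* **Oculomotor signal.** After each onset the eye keeps fixating, then
  saccades to the target after the participant's latency (per-trial SD
  30 ms); saccade duration follows the main sequence (21 ms + 2.2 ms/deg)
  with a raised-cosine position profile.  Dwells are broken into
  sub-fixations of gamma-distributed duration (shape 4, mean = the
  participant's fixation-duration parameter) whose centres shift by
  ~85 px (≈1.3°) instantaneously between samples — above the fixation
  dispersion threshold, below a target-directed saccade amplitude.
  Gaussian jitter (participant-specific SD) rides on every dwell sample.
* **Blinks and dropouts.** A Poisson process at the participant's blink
  rate; each blink blanks ~150 ms of samples (validity gaps).  Isolated
  single-sample dropouts occur at 1 % to exercise QC.
* **Pupil.** Baseline + 0.06 mm per workload level + Gaussian noise with a
  participant-specific SD.
* **Population structure.** Latent parameters are drawn per participant
  from truncated normals.  CN means (SDs): latency 200 (20) ms, sub-fixation
  duration 400 (80) ms, jitter 8 (1.5) px, blink rate 15 (7)/min, blink
  duration 150 (30) ms, pupil 3.5 (0.4) mm, pupil noise 0.10 (0.025) mm,
  base think time 2000 (400) ms with workload multipliers (1.0, 1.2, 1.5);
  age 64.9 (8.9) y.  PMCI applies the effect sizes: +40 ms latency, ×1.3
  fixation duration, ×1.4 jitter, +4 blinks/min, ×1.5 pupil noise, ×1.25
  think time; age 67.9 (9.1) y.  These magnitudes are package design
  defaults sized for stable pipeline recovery — they are not empirical
  estimates.
* **DRS.** CN ~ N(142.1, 1.5) truncated to [140, 144]; PMCI ~ N(135.9, 3.2)
  truncated to [100, 139]; rounded to integers.  Truncation enforces the
  label rule by construction; it also pulls both group means slightly
  down, so the expected cohort mean DRS is ≈ 140.67 rather than the
  untruncated 140.9.

The *null configuration* (`null_cohort_spec`) equalizes every
group-conditional distribution — including age — except the DRS itself,
which only sources the label.  Under it, any downstream discrimination is
spurious by construction.

What the generator does **not** emulate: calibration drift, smooth pursuit,
microsaccades, head motion, answer correctness, pupil light reflexes, or
realistic covariance between latent parameters (they are drawn
independently).  Passing tests on synthetic cohorts therefore demonstrates
that the pipeline recovers the structure this model encodes — not that the
feature set separates clinical groups in real data.

## 3. Quality control

* **Tracking ratio** = valid samples / all samples, computed on the raw
  acquisition flags before any interpolation (it is an acquisition-quality
  gate).  Recordings below 0.80 are excluded; exactly 0.80 is kept
  ("meeting" the threshold).
* **Despiking.** A sample on the valid chain is a spike when the angular
  velocity both into and out of it exceeds 1000 °/s (an out-and-back
  excursion); chain endpoints use their single defined velocity after
  interior spikes are removed.  Invalid runs no longer than 50 ms are
  re-filled by linear interpolation between the nearest valid neighbours
  (one-sided at recording boundaries).  The 50 ms cap is deliberately below
  the 75 ms blink minimum so interpolation can never fabricate gaze through
  a blink.  Original validity flags are preserved in `raw_valid`.
  Despiking is idempotent.
* **Filtering.** A window-3 running median over valid gaze coordinates is
  applied by default and can be switched off; the acquisition pipeline
  names filtering without fixing a type.
* **Blinks** are maximal invalid runs with duration (run length × nominal
  sample interval) in [75, 500] ms, detected on the raw flags.  Longer
  runs are treated as signal loss, not blinks.

## 4. Event classification and features

**I-DT.** Fixations are grown from minimum-duration windows (default
100 ms) whose dispersion — the maximum pairwise sample distance, in
degrees — stays ≤ 1.0°; the window extends until violated.  Invalid runs
split the recording and events never join across them.  Between consecutive
fixations whose centroids are more than the threshold apart, the interval
becomes a saccade, provided it contains at least one intervening sample
(adjacent fixations produced by an instantaneous centre shift are not
movements).  Saccade timing is then delimited *within* the interval by a
peak-anchored velocity criterion: from the interval's velocity peak, the
bounds extend while velocity stays above 60 °/s.  This keeps saccade onsets
from absorbing stationary padding when a dwell was too short to qualify as
a fixation.

**Units.** Pixels convert to millimetres via the physical diagonal
(0.1614 mm/px, square-pixel assumption) and to visual angle by exact
arctangent at 600 mm.

**Latency.** For each stimulus onset, latency is the start of the first
saccade in [onset, next onset) pointing within ±45° of the direction from
its start point to the new target.  Two robustness gates extend that rule:
saccades smaller than 2° are ignored (fixational micro-shifts are not
target acquisitions), and latencies above 800 ms are discarded as artifacts
— when a blink obscures the true saccade the next directional match can be
seconds late, and a single such value dominates a participant's mean.
Stimuli without a qualifying saccade are missing and excluded from the
mean/SD.

**Feature definitions** where the protocol names a quantity without
defining it: fixation *size* is the maximum pairwise sample distance within
the fixation (mm); fixation *area* is the convex-hull area of its samples
(mm², zero for collinear samples); saccadic *plane* is assigned from the
direction angle (±22.5° bins around the cardinal axes), so real recordings
without a task script are supported.  Feature SDs are population SDs (a
single event has zero spread).  Latency statistics pool all stimuli.  Blink
rate normalizes by the full recording duration.  Missing components (a
plane with no saccades, a position with no fixations) yield NaN with a
warning.

## 5. Preparation, selection, models

Order of operations: log transform → stratified split → (imputation) →
SMOTE → standardization → selection → models.

* **Log transform.** The default policy transforms exactly the features
  whose canonical name carries the `(Log-)` designation; a data-driven
  policy (|adjusted Fisher–Pearson skewness| > 1, computable on training
  only) is available.  Zeros receive a 10⁻⁶-of-median offset; negatives
  are an error.
* **Split.** Per-class test counts are rounded class shares reconciled to
  the rounded global 20 % by largest remainder (166/40 → 33/8).  The
  printed study split (135/29 train, 31/11 test) is not reachable by any
  exact 80/20 rounding rule, so explicit count overrides are supported and
  used when reproducing those tables.
* **Imputation.** Training-median imputation fills missing features; the
  medians are part of the saved transform state.  (The models cannot accept
  NaN, and sparse planes/blinks legitimately produce them.)
* **SMOTE.** Implemented in-package: each synthetic sample is
  x + u·(neighbour − x), u ~ U(0, 1), with the neighbour drawn from the
  sample's k = 5 nearest minority neighbours (Euclidean, raw feature
  scale — balancing precedes standardization, following the stated
  order).  Minority count is raised exactly to the majority count; k is
  reduced with a warning when the minority is small.  Synthetic rows are
  flagged; the test partition is never touched.
* **Standardization** is fitted on the (balanced) training table; zero-
  variance features keep SD 1 with a warning.  All transform state is a
  pure function of the training split.
* **Selection.** Step 1: connected components of the |Pearson r| > 0.8
  graph (components rather than cliques, for determinism; clique semantics
  would make group membership order-dependent), then one 500-tree Random
  Forest fitted on all features; within each multi-feature group only the
  highest-importance member survives (ties break toward canonical feature
  order).  Step 2: per-feature depth-3 decision tree scored by mean
  5-fold stratified cross-validated ROC-AUC (resubstitution mode available);
  features with AUC ≤ 0.5 are dropped.  If the filter empties the set
  (expected on null data about a quarter of the time), the single
  best-scoring feature is retained so a model can still be fitted.  Note
  the filter is weak against noise by construction: a label-independent
  feature scores above 0.5 roughly half the time, which is the behaviour
  of the stated rule, not an implementation artifact.
* **Models.** Logistic regression: scikit-learn defaults (L2, C = 1,
  L-BFGS), no class weights; the PMCI probability is thresholded at 0.45
  and 0.50 (≥ counts as positive).  KNN: Euclidean, uniform weights,
  k ∈ [3, 10] maximizing mean 5-fold cross-validated F1 on training
  (accuracy criterion available); ties prefer smaller k.
* **Evaluation.** The fitted model is frozen; the test set is resampled
  with replacement 1000 times (replicates with no positive case are
  redrawn and counted); each metric's mean and 2.5/97.5 percentile
  interval is reported, with the same replicates shared across metrics.
  AUPRC uses the average-precision formulation (no trapezoidal
  interpolation); an all-positive resample scores 1 by convention.
  Zero-denominator confusion metrics report 0 with a degeneracy flag,
  never NaN.

Age is included as a feature in every feature-set mode (combined,
time-only, eye-only) and is eligible for removal during selection like any
other feature.

## 6. Validation experiments and their problem sizes

The test suite validates the pipeline on synthetic cohorts at sizes chosen
to make each property measurable:

* **Parameter recovery** uses a 200-participant cohort with 24-sequence
  sessions (~3 min each).  Session length follows from counting noise: a
  blink-rate estimate over time T has SE √(rate/T), which must sit well
  below the ~6.7/min population SD for a correlation above 0.9 to be
  achievable at all; ~3 minutes gives SE ≈ 2.2/min.
* **Null calibration** uses twenty 206-participant zero-effect cohorts.
  With 8 positives in a 41-sample test set, average precision under random
  ranking has expectation ≈ 0.26 — above the 0.194 prevalence.  That
  small-sample bias is a property of the estimator; the ±0.1 band around
  prevalence accommodates it at this test size.
* **Directional properties** (balancing raises logistic-regression recall;
  the combined feature set's AUPRC is at least each single set's) are
  means over twenty 206-participant default-effect cohorts.

## 7. Known limitations

* The generator's independence of latent parameters makes correlated
  features arise only through shared mechanics (e.g. think time drives both
  time features and fixation counts); real oculomotor features are more
  strongly collinear, so the correlation-grouping step is exercised less
  on synthetic data than it would be on clinical data.
* Default effect sizes produce strong separability; near-ceiling metrics on
  small test sets are expected and intended (the evaluation machinery, not
  the difficulty of the task, is what synthetic runs validate).
* The I-DT dispersion threshold (1.0°) and minimum duration (100 ms) are
  field-standard defaults, configurable; results on real data are known to
  be sensitive to them.
* Bootstrap intervals quantify test-set resampling variability only; the
  trained model and the split are fixed, so split-to-split variability is
  not captured.
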