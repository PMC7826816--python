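# Methods

This note records the modeling choices, conventions and tunable
parameters behind `premac`, and what the synthetic test bed does and
does not establish.

## Orientation and kinematics conventions

Angles are named by rotation axis — roll about x (front), pitch about
y (subject's left), yaw about z (up) — and a segment's body-to-parent
rotation is `R = Rz(yaw) · Ry(pitch) · Rx(roll)` acting on column
vectors (roll applied first).  This is the unique axis-angle assignment
under which (a) a resting accelerometer reading `a = Rᵀ (0,0,1)` is
independent of heading, and (b) the tilt-compensated compass formula
used for yaw is the exact inverse of the rotation applied to a
north-pointing field.  The extraction formulas

    roll  = atan2(a_y, a_z)
    pitch = atan2(−a_x, √(a_y² + a_z²))

use two-argument arctangents throughout, so yaw covers the full
(−π, π] range.  Pitch is confined to (−π/2, π/2) by the gravity
decomposition; the synthesize→recover round trip is exact (< 1e−9 rad)
on that domain and is tested as such.  Sign convention: at rest the
accelerometer reads +1 g opposite gravity.  The magnetometer is treated
as arbitrary-but-consistent units with a field pointing north and
downward; no hard/soft-iron calibration is modeled.  The IMUs' gyros
are unused — orientation comes from accelerometer + magnetometer only,
with no complementary/Kalman fusion, so orientation estimates during
high linear acceleration are noisy.  That noise is part of the feature
set, not corrected.

Forward kinematics chains homogeneous transforms `H = [R d; 0 1]` over
a joint tree rooted at the spine base (+x front, +y left, +z up); link
translations are per-garment-size constants in mm, loadable from YAML.
Adjacent-joint distances are invariant under any pose (rotations
preserve norms); `SkeletonPose.validate` checks this to 1e−6 mm and
the test suite checks positions against an independently coded
matrix-composition oracle to 1e−9 mm.

## Preprocessing

* **Filters.** Unless stated otherwise all filters are 4th-order
  Butterworth applied forward–backward (`sosfiltfilt`), i.e. zero
  phase.  Zero phase matters because features are aligned against
  behavioral timestamps: a causal filter's group delay would shift
  every label boundary.  The wrist accelerometer (32 Hz) gets a 10 Hz
  low-pass; BVP (64 Hz) a 1–8 Hz band-pass before beat detection.  The
  15 Hz body-motion stream has a Nyquist frequency of 7.5 Hz, below
  the nominal 10 Hz acceleration cutoff, so a 10 Hz low-pass is
  undefined there and the stream is used unfiltered; the filter API
  rejects any cutoff ≥ Nyquist rather than silently clamping.
* **Corruption scrubbing.** Rows with non-finite entries or
  accelerations beyond ±16 g (the IMU full-scale range) are marked
  missing wholesale — a corrupted wireless packet invalidates the
  sample — and reported per channel.  Missing runs of ≤ 2 samples with
  valid endpoints are bridged linearly; longer runs stay missing and
  those instants are excluded from the feature timeline.
* **Imputation (face/head stream only).** A missing numeric value is
  replaced by the mean of the k = 20 timestamp-closest available
  samples of that channel; a missing facial score by their modal class,
  ties broken by the single nearest sample.  "Closest" is bilateral
  (both directions in time) — the pipeline is offline, so there is no
  reason to restrict to past samples — and when fewer than k values
  exist, all are used.  Imputation never alters observed values.

## Features

* **Activity level** is the mean acceleration-vector magnitude over a
  1 s centered window (per body segment, and implicitly for the
  wrist via its filtered accelerations).  The averaging denominator is
  the window's sample count; a fixed-constant divisor is available as a
  strict toggle but only rescales the feature.
* **Heart rate**: systolic peaks from `scipy.signal.find_peaks` on the
  band-passed BVP (minimum spacing 0.3 s, prominence 0.8 SD), then
  HR = 60 / mean(IBI) over a 10 s trailing window updated at 1 Hz;
  windows with fewer than two beats are missing and the value holds
  until the next update at fusion time.
* **EDA decomposition**: SCL is a 0.05 Hz zero-phase low-pass of the
  conductance, SCR the exact residual, so SCL + SCR reconstructs the
  input to machine precision.  This is a deliberately simple,
  reconstructible split; deconvolution-based SCR models are out of
  scope.
* **Fusion** uses the body-motion timeline as the basis; every other
  feature takes the value of its timestamp-closest sample (ties to the
  earlier one), verbatim, with no interpolation.  The torso's angles
  are the arithmetic mean of the three back IMUs (adequate while yaw
  stays away from ±π; a circular mean would be needed for free
  spinning), and its activity level the mean of their activity levels.
  The default ("paper-strict") feature set has exactly 32 columns; an
  extended mode adds the eyes-closed and mouth-open scores.

## Labels and rebalancing

Label 1 ⇔ the row's timestamp lies within [t_precursor − W, t_precursor],
inclusive at both ends, for any precursor; W defaults to 90 s.  Rows
are labeled by the time rule only — condition (evocative vs
reinforcing) is not consulted, and rows between a precursor and the
next calm period keep label 0 unless covered by a later precursor's
window.  Class balance is left natural (about 6:4 at W = 90) except in
the window-sensitivity analysis, where the minority class is duplicated
with replacement (seeded) to exactly 1:1 before cross-validation; the
duplicates can land in different folds, which is mildly optimistic, but
the rebalance-then-validate order is kept as the protocol being
reproduced specifies.

## Classifiers and validation

Default hyperparameters (none are tuned): RF 100 trees; SVM RBF; kNN
k = 5; CART decision tree; linear discriminant analysis; Gaussian naive
Bayes; MLP with one hidden layer of 64 units.  Distance- and
margin-based families are standardized in-pipeline; trees are not.
Individualized performance is stratified 5-fold CV (shuffled, seeded);
an 80/20 stratified holdout with its confusion matrix is a separate
command.  Confusion matrices follow the standard convention
(actual-yes/predicted-no = FN).  Group performance is
leave-one-subject-out; subjects with a single class are flagged and
skipped as test folds.  Feature importances are scikit-learn's
impurity-based RF importances (non-negative, summing to 1), aggregated
per modality by summation.

## The synthetic cohort

The generator is an invented signal model — no claim of physiological
realism beyond what the features can sense:

* **Protocol layer.** A stochastic child/therapist policy drives the
  session state machine: calm onset latency Γ(4, mean 12 s) after
  reinforcement begins, the mandated 90 s of continuous calm plus an
  Exp(5 s) hold, a Γ(4, mean 15 s) latency from evocative-condition
  onset to the first precursor, bursts of 1 + Poisson(1.5) precursors
  spaced 5 + Exp(23) s, then reinforcement after 5 s.  Session
  durations default to 12.05/11.37/10.02/10.71/10.05 min in the fixed
  control–test–control–test–test order.  These constants were chosen so
  that a visit reproduces the aggregate statistics the pipeline is
  designed around: ≈ 26 precursor episodes per ≈ 54 min visit and
  ≈ 40% positive rows at W = 90.  Every generated log replays through
  the state machine with zero violations by construction.
* **Escalation envelope.** Each precursor is preceded by a 90 s (by
  default) escalation ramp rising from a 0.3 floor at onset to 1 at
  the event.  The step-plus-ramp shape makes the window boundary
  learnable at W ≤ 90 (the classifier can threshold intensity) while
  rows more than 90 s out carry no signal at all — which is what makes
  accuracy at W = 120 collapse, by construction rather than tuning.
* **Signals.** Limb motion is sinusoid-plus-noise in angle space,
  amplitude scaled by (1 + gain·env); raw IMU readings are synthesized
  through the exact inverse orientation model plus band-limited dynamic
  acceleration (which is what the activity level senses) and ≈ 1°
  white angle noise.  BVP is a template-pulse train whose rate is
  base + rise·env bpm; EDA is a drifting tonic level plus
  exponential-decay SCR transients arriving at base·(1 + gain·env) per
  minute; facial scores are categorical draws from per-state tables;
  head rotations scale like limb motion.  Face tracking drops out in
  two-state Markov bursts (mean 1.5 s) with stationary rate 26.9%, and
  0.3% of IMU rows are corrupted with non-finite or out-of-range
  values.
* **Cohorts.** Subjects scatter around the population profile with a
  spread proportional to `heterogeneity`: which body segments express
  escalation (with a dominant-side boost), baseline posture, heart-rate
  baseline and rise, SCR gain.  At heterogeneity 0 all subjects share
  one profile and differ only in noise seeds — the regime where
  individualized and group models should agree; at 1 the group model
  degrades sharply, which is the qualitative contrast of interest.

**What passing tests show — and don't.** On this generator the
pipeline recovers planted signatures nearly perfectly, so the green
suite demonstrates *correctness of the machinery* (kinematics, filters,
labeling, validation schemes, protocol logic), not clinical
performance.  Real recordings have motion artifacts in BVP, EDA
drift unrelated to arousal, non-stationary baselines, imperfect
observer timestamps, and escalation dynamics far messier than a fixed
90 s ramp; accuracies on real data will be lower and cannot be inferred
from these simulations.

## Problem sizes and numerical choices

The demonstration script (`scripts/acceptance.py`) and the end-to-end
tests use a 3-subject heterogeneous cohort at half-length sessions
(≈ 24k fused rows per subject) — the package's chosen demo size; full
length visits run the same code path.  All randomness flows from
explicit integer seeds (cohort, model, protocol and permutation seeds
derived via `SeedSequence`); equal seeds give byte-identical streams,
files and reports.  Stream files store floats at 17 significant digits
so write→read round trips are exact.  Degenerate inputs fail loudly:
zero accelerometer or magnetometer vectors, cutoffs at or above
Nyquist, all-missing channels, single-class datasets, windows ≤ 0 and
malformed logs all raise typed errors rather than propagating NaNs.

## Known limitations

No lower-body model; no magnetometer calibration; no sensor-fusion
filter for orientation; no BVP motion-artifact handling beyond the
band-pass; no HRV/frequency-domain or skin-temperature features; no
hyperparameter search, calibration or ROC analysis (accuracy is the
reported metric); the tablet UI, live device drivers and clinical
procedures around the protocol are out of scope.
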