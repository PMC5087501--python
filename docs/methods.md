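# Methods

This note documents the models and procedures implemented in
`hiermotion`, the conventions frozen where the method leaves choices
open, what the synthetic generators do and do not emulate, and known
limitations.

## Windows and streams

All analysis operates on fixed 6-second, non-overlapping windows
assigned by the half-open interval `[start, start + 6 s)`; a trailing
partial window is dropped. Inertial streams are 50 Hz with
accelerometer in g (±2 g) and gyroscope in rad/s (±4 rad/s);
out-of-range samples are clipped to the sensor range with a logged
warning rather than rejected, since isolated saturated samples are
normal watch behavior. Skeleton tracks carry 12 named joints as 3-D
camera-frame positions in meters, +y up; missing joints are NaN rows
with an explicit mask.

## Sensor-to-skeleton binding (NCC mapping)

Both modalities are reduced to a binary "watch hand active" indicator:

1. **Velocity.** Gyroscope: per-sample norm of the three axes (rad/s).
   Image: per-frame norm of the watch-hand joint's positional first
   differences (m/frame). The watch hand defaults to the left hand and
   is configurable.
2. **Common clock.** The two native rates (50 Hz vs 30 Hz) are aligned
   by aggregating each series to 1 Hz with a per-interval *maximum*.
   The maximum, unlike the mean, preserves sub-second hand motions at
   either native rate. Empty or all-missing intervals read 0.
3. **Smoothing.** A median filter (default length 5 samples at the
   comparison rate, odd length required, edge replication) suppresses
   isolated spikes without blurring burst edges.
4. **Binarization.** Strict `>` thresholding at `T_gyro` (default
   1.3 rad/s) and `T_image` (default 0.023 m/frame).

Per 6-s window the normalized cross correlation
`N = Σ GT·IT / √(Σ GT²·Σ IT²)` is computed for every
(skeleton, sensor) pair. `N` is undefined (NaN) when either series is
identically zero; undefined values count as 0 for voting. A window is
*invalid* — and casts no vote — when every candidate's defined `N` lies
within ε (default 0.05) of 0, or when all candidates are undefined:
nobody moved, so the window carries no identity information. Every
valid window votes for its argmax sensor (a tied window casts no vote),
and each skeleton is assigned the sensor with the most votes. Final-
tally ties are reported as unresolved rather than guessed. Assignment
is per-skeleton independent; an optional exclusive mode solves a
one-to-one assignment over the vote matrix instead.

**Threshold fitting** maximizes
`Σ GT·IT / max(Σ GT, Σ IT) − Σ GT·IT / D` over a grid
(`T_gyro ∈ [0, 4]` step 0.05, spanning the gyro range;
`T_image ∈ [0, 0.1]` step 0.001, bracketing the default) on points
pooled across all supplied same-subject pairs. The first term rewards
agreement of the two active sets; the second penalizes thresholds so
low that everything looks active. Ties break toward the smallest
`T_gyro`, then the smallest `T_image`; a grid cell where neither
indicator fires scores −∞.

## Motion features (26 per window)

Per channel (ax, ay, az, gx, gy, gz): mean, population variance (÷N,
matching the 1/N convention of the other formulas), range
(max − min), and spectral energy. Plus one absolute-change statistic
per sensor triple:

    AC = (1/N) · Σ_{axes} Σ_{i=2..N} |v_i − v_{i−1}|

The sum has N−1 terms per axis but is divided by N, keeping the printed
normalizer; the difference is a factor (N−1)/N ≈ 0.997 at N = 300 and
irrelevant to any classifier. Spectral energy is the DC-excluded
periodogram energy `Σ_{k≠0} |X_k|² / N²`; excluding DC makes a constant
signal score 0, and a pure cosine of amplitude A scores A²/2 (by
Parseval this normalization equals the channel's population variance —
the definition is kept separate because the frequency-domain form is
the conventional one in inertial HAR feature sets and stays meaningful
under any future band restriction). Feature order is frozen and
exported (`MOTION_FEATURE_NAMES`); models are only portable under it.

## Visual features (70 + 80 per window)

**Shape histogram.** Every tracked joint in every frame with an
observed hip center is expressed in hip-centered spherical coordinates:
zenith θ ∈ [0, π] measured from the +y camera vertical, azimuth
φ ∈ [0, 2π) in the x–z plane counter-clockwise from +x. θ is split
into 7 equal bins, φ into 10, and the 70 counts are normalized to sum
1. The hip center itself sits at radius 0, where the angles are
undefined, and is skipped — effectively 11 contributing joints. The
histogram is invariant to frame order and to translating the whole
skeleton.

**Edge histogram (EHD).** A grayscale hand-region crop (≥ 16×16 px) is
split into 4×4 sub-images, each scanned in non-overlapping 2×2-pixel
blocks. Each block is classified by the strongest of five zero-sum
oriented operators (vertical, horizontal, 45°, 135°, non-directional)
when the response exceeds a threshold (default 11, the MPEG-7 reference
value on 8-bit intensities); per-sub-image 5-bin histograms are
normalized by block count. Zero-sum operators make the descriptor
invariant to constant intensity shifts. Hand-crop *acquisition* from
RGB frames is out of scope: the pipeline accepts crops or precomputed
80-bin descriptors, and the synthetic generator supplies descriptors
directly.

The visual vector is the 150-element concatenation
[shape histogram ‖ EHD]; a 70-element shape-only variant exists for
runs without crops.

## Automatic group selection

A partition `C = {c_1..c_M}` of the N activity labels is scored by

    Q(C) = (Σ_m T(c_m)) / M − 1/M

where `T(c_m)` is the recall of group m under an M-class classifier
evaluated with stratified k-fold cross-validation (k = 5 default).
Reading the score as mean(T) − 1/M is the interpretation that both
penalizes needlessly fine partitions at equal mean accuracy and
produces an interior peak in M; T as *cross-validated recall* (rather
than training accuracy) is what makes the stopping rule meaningful.
The classifier is injectable; the default is a linear-kernel SVM,
C = 1, class-balanced weights.

The search evaluates all `2^(N−1) − 1` two-group partitions, then
repeatedly generates candidates by splitting exactly one group of the
incumbent into two non-empty subsets (labels separated in an earlier
round are never regrouped), advancing while the round's best Q
*strictly* exceeds the previous round's and M < N. Equal-Q candidates
resolve to the first in canonical order (groups sorted by smallest
member). The best partition seen is returned together with the full
per-round trace. The search is greedy: it can in principle commit to a
2-group split that no refinement can repair; this is the price of
avoiding the Bell-number-sized exhaustive search and is inherited from
the method's design.

## Hierarchical classification and fusion

Layer 1 maps motion features to group probabilities; layer 2 is one
global N-activity classifier over visual features (not per-group
classifiers). Both default to linear SVMs with Platt-calibrated
probability outputs (5-fold internal calibration); any probabilistic
classifier can be injected. A single-group partition degenerates layer
1 to a constant. The fused score of activity a with (unique) containing
group g_a is `P(a|image)·P(g_a|sensor)`; the argmax is returned with
ties broken in canonical (sorted) label order. Fused scores are
non-negative and sum to at most 1; `predict_proba` renormalizes them.

Without a camera view, a single-layer calibrated SVM over motion
features covers exactly the four motion-detectable activities
(walking, standing, sitting, running); fitting it with any other label
set is an error. A dispatcher routes each window by whether a visual
row is present and records the path taken. Comparison baselines (flat
concatenated-feature single layer, sensor-only, image-only) are
available as training modes.

## Evaluation

Confusion matrices are integer counts with rows = true labels. Per
class: precision TP/(TP+FP), recall TP/(TP+FN), F1 their harmonic mean
with the 0/0 → 0 convention; a never-predicted class is flagged and
scored precision 0. The macro F1 is the unweighted mean (with balanced
classes micro = macro). Values are reported rounded to 3 decimals;
full precision is retained internally. Leave-one-subject-out CV holds
each subject out in turn and *sums* the per-fold confusion matrices,
so the summed matrix is order-invariant. An 8×8 benchmark summed LOSO
confusion matrix for the eight-activity task ships as a frozen
regression fixture for the metric arithmetic (per-class F1 row 0.799 –
0.902, macro 0.839).

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (spec, seed) and produce streams
that pass all stream validators.

* **Sessions** (`gen_session`): per-activity profiles set the
  accelerometer mean vector and noise (standing pins one axis at +1 g —
  the watch axis parallel to gravity), optional locomotion oscillation,
  and a two-state on/off hand-burst process with exponential dwell
  times driving both the gyroscope magnitude and the skeleton hand
  oscillation, so the cross-modal co-activity the mapping relies on is
  physically present. Skeletons are a static standing/sitting base pose
  plus activity-specific hand placement, hand oscillation during
  bursts, and 1.5 mm joint jitter.
* **Scenes** (`gen_scene`): n subjects over 6-s slots; outside overlap
  slots exactly one subject is active, in overlap slots all subjects
  share *the same* burst indicator, so those windows carry no identity
  information by construction. Overlap 0 gives disjoint schedules;
  overlap 1 makes mapping undecidable, mirroring the invalid-interval
  phenomenon. Default scene: 2 subjects, 15 minutes.
* **Planted features** (`gen_grouped_features`): the motion block gives
  every activity of a group the same mean (between-group separation 6
  against unit noise, within-group 0); the visual block separates
  within-group positions (separation 3) but aliases activities at the
  same position across groups. Motion alone resolves groups, visual
  alone resolves within-group position, only their combination resolves
  the activity — the structure the two-layer model exploits. The
  default planted partition is 5 groups over 8 labels:
  {SD}, {CW, ST}, {RD}, {CL}, {BR, DK, ET}.

Not emulated: soft-tissue and orientation drift of real watches,
skeleton-tracking failures and hand-position jumps, camera-distance
effects, correlated inter-subject behavior beyond the overlap model,
and real RGB appearance (EHD inputs are prototype-plus-Dirichlet-noise
descriptors; a striped-image generator exercises the image path).
Passing tests on these fixtures therefore demonstrates correctness of
the algorithms and the claimed qualitative behaviors (mapping recovery
degrading with schedule overlap, Q peaking at the planted group count,
hierarchy ≥ flat on group-structured data) — not field accuracy on
real recordings.

## Numerical choices and degenerate inputs

* Undefined NCC (zero denominator) is NaN, treated as 0 in voting.
* Binarization uses strict `>`; grid tie-breaks and argmax tie-breaks
  are deterministic as described above.
* Joints within 1e-12 m of the hip center are skipped in binning; θ
  and φ bin indices are clamped at the upper boundary (θ = π falls in
  bin 6, φ wraps modulo 2π).
* Population variance (ddof = 0) throughout.
* Windows shorter than 2 samples, empty skeleton files, unknown joint
  names, non-monotone timestamps, label sets not covered by a
  partition, and groups smaller than the CV fold count all raise
  explicit errors.

## Problem sizes in the shipped tests

Unit and property tests run on windows of 16–300 samples and label
sets up to 8. End-to-end checks use twenty 15-minute two-subject
scenes for mapping, ten seeds of 8 labels × 50/class for
partition-search recovery, and ten seeds of 8 labels × 60/class for
the hierarchy-vs-flat comparison — sizes at which every stochastic
claim is comfortably resolved while the whole suite runs in a few
minutes on one CPU.
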