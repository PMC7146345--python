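# Methods

This note documents the model, the synthetic data it is exercised on, the
numerical choices, and the limits of what the tests show.

## Signal model and preprocessing

The input is a uniformly sampled 6-axis record: accelerometer in m/s²,
gyroscope in °/s, nominally 50 Hz (T = 0.02 s). Processing is buffered:
the stream is cut into independent buffers of `features.chunk_samples`
(default 55 samples ≈ one repetition), inside which the gravity estimate,
the integrators and the angle filter all restart. This mirrors how a
wristband MCU consumes the stream and is load-bearing on long traces: a
global gravity mean and an unreset double integrator drift without bound
on multi-movement recordings.

Each buffer is median-filtered per channel (window 3, replicated edges)
and fused. The complementary filter trusts gyro integration over short
horizons and corrects it with the *running average* of the
accelerometer-derived angle — averaging matters because the instantaneous
accelerometer angle is motion-corrupted, while its mean over an
oscillation cycle tracks the quasi-static wrist attitude:

    theta[t] = alpha * (theta[t-1] + gyro[t] * T) + (1 - alpha) * mean(theta_acc[0..t])

with `alpha = 0.98` (time constant 1 s at 50 Hz), roll/pitch from the
arctangent of gravity components, and yaw by pure gyro integration
(unobservable from gravity). The same convex weighting on the
acceleration channels — accelerometer reading vs the gravity vector
predicted by the gyro-propagated attitude — yields the denoised gravity
estimate whose magnitude equals 9.8 m/s² exactly for a noise-free
stationary record. A scalar unscented Kalman filter on
`ACC_k = ACC_{k-1} cos²(theta_k) + w_k`, `z_k = ACC_k + v_k`
(sigma-point parameters α=1e-3, β=2, κ=0) is included as the comparison
baseline; the complementary filter is the production path.

Angles are degrees throughout.

## Feature streams

Four per-sample magnitude streams: ASMV (acceleration norm), VSMV
(cumulatively integrated, gravity-removed velocity norm), DSMV (doubly
integrated displacement norm) and θSMV (fused-angle norm). Integration is
rectangular (running sum × T) — the MCU-friendly form; trapezoidal
integration would change values by O(T) and nothing downstream depends on
that difference. Gravity removal subtracts the per-buffer mean
acceleration vector; the residual noise random walk is bounded by the
buffer length.

Streams are segmented by a 10-sample/5-step sliding window and each
window contributes its four stream maxima. A fixed 155-sample buffer
(3.1 s) under this windowing yields 30 windows and a 120-dimensional
assembled vector (`features.assemble_buffer_vectors`); the fitted
pipeline, however, feeds layer 1 the per-window 4-vectors directly. The
buffer form cannot serve as the classification unit here: a single
test instance is one repetition (50–60 samples), far shorter than one
buffer, and fivefold cross-validation over single instances would starve
the deeper layers. The per-window form is the same information at the
granularity the deeper layers need.

## The four-layer hybrid clustering model

Everything is fitted without labels; class identities attach to
recordings only through the known movement of each training recording.

**Layer 1 (encode).** Window 4-vectors are standardized per stream
(divide by the pooled standard deviation — the streams span ~3 orders of
magnitude in physical units, and unstandardized PCA would collapse onto
the angle stream), reduced to one scalar by 1-D PCA (unit loading,
largest-magnitude component positive), and quantized by K-means with
k₁ = 70. Clusters are relabelled in increasing center magnitude, so the
code is a rank; encoding maps a scalar to the nearest sorted center.

**Layer 2 (decompose).** Non-overlapping pairs of consecutive ranks are
clustered by K-means (k₂ = 20) and relabelled by descending frequency
(ties to the smaller original label). A pair pattern is a *sub-feature* —
a recurring micro-pattern such as the rise, peak or fall of a swing.
Overlapping pairs were evaluated and rejected: the transition pairs they
introduce add within-instance label diversity and reduce separability.

**Layer 3 (summarize).** Per movement, a 4/2 window over the sub-feature
label stream gives (max, min, mean) triples, compressed by K-means with
k₃ = 8 into that movement's sub-feature centers.

**Layer 4 (separate).** DBSCAN (Euclidean, eps = 0.2, min_pts = 2) over
all centers. A density cluster whose members span ≥ 2 movements is a
common sub-feature and is discarded; noise points and single-movement
clusters are the movement's exclusive candidates. The eps default is
geometric: window means of the label stream are quantized in steps of
1/4, so centers of *distinct* label patterns are at least ~0.25 apart
while centers of the *same* pattern fitted in different movements fall
within ~0.2. A larger eps (1.0 was tried) chains distinct patterns
across movements and can leave a movement with no exclusive center; when
that still happens, `fit()` halves eps (≤ 4 times) before failing, per
the layer's error contract.

**Greedy minimal signatures.** Starting from all exclusive candidates,
backward elimination repeatedly drops the center whose removal maximizes
the proportion criterion (below), while the criterion stays within
`greedy_tol` of its best value and every movement keeps one center. The
default tolerance is 0 — drop only what costs nothing on the training
criterion. A positive tolerance (0.01 was tried) discards rare-variant
centers whose test segments then fall to neighbouring movements. The
scan order (movement id, candidate position) makes the search
deterministic; the criterion is evaluated on a precomputed
segment-by-candidate distance matrix, which is algebraically identical
to re-classifying per trial.

**Classification and thresholds.** A segment triple is assigned to the
movement of its nearest signature center; distances are reported
normalized by the per-segment maximum across movements. The rejection
threshold per movement is the 99.5th percentile (method `higher`) of the
movement's own training-segment distances, floored at half the gap to
the nearest other movement's signature. The threshold exists to filter
out-of-vocabulary actions; within the closed nine-class protocol, a
rejected in-vocabulary segment is an error, which is why the threshold
sits at the edge of the training distribution rather than at the 95th
percentile.

**Counting.** Run-length encoding of the segment labels; runs of at
least `min_run = 2` segments increment the movement's count, UNKNOWN
runs never count. These are *bouts*: back-to-back repetitions of one
movement form a single run, so a continuous 20-repetition recording
counts one bout. Counting individual repetitions inside a bout would
need a periodicity detector, which is out of scope.

**Determinism.** One master seed; per-layer seeds at fixed offsets;
K-means runs 10 deterministic k-means++ restarts and keeps the lowest
SSE (a single restart showed fold-to-fold scatter from local optima);
and every K-means input pool is canonically sorted (scalars ascending,
pairs/triples lexicographically), so a permutation of the training
instances cannot change any fitted parameter.

## The proportion criterion and evaluation

Without point labels, accuracy is surrogated by comparing, per
recording, the fraction of points predicted as the recording's movement
with the expected fraction from the repetition annotations; the scalar
score is 1 − the mean absolute difference. This criterion drives the
greedy search and the k₁ sweep. Cross-validation is stratified fivefold
over the 900 single-repetition instances by (class, subject); each
instance is tested exactly once, labelled by majority over its segments,
with UNKNOWN counted as an error. Instance-level and point-level
accuracy are both reported (they differ by < 0.01 on the synthetic
protocol); F1 is macro-averaged over the nine classes.

## The synthetic data generator

No recording from the original five-subject collection is deposited, so
the generator emulates the protocol: 5 subjects × 9 movements × 20
tests, one repetition drawn uniformly from 1.0–1.2 s at 50 Hz,
repetitions of one movement concatenated into a continuous set with true
boundaries recorded, and a per-subject amplitude multiplier drawn once
(±10%).

Each repetition is, per axis: a gravity offset along the class's nominal
wrist attitude, a fundamental-plus-harmonic oscillation (harmonic weight
0.35), a repetition-scale swing bump (sin² over the repetition, half the
oscillation amplitude) and white Gaussian noise with σ = 20% of the
class's largest axis amplitude (both sensors). The swing bump is what
gives the integrated velocity/displacement streams genuine signal; a
5–7 Hz oscillation alone integrates to almost nothing.

The nine classes form a graded intensity ladder (amplitude ratio ~1.6
between adjacent rungs, walking 0.85 m/s² up to a ~4 g smash) with
three scale-matching choices documented in the class-table YAML:
oscillation frequencies in a narrow 5–7.3 Hz band so the 0.2 s window
maximum reads the envelope rather than the phase; wrist-attitude tilt
growing as √amplitude (0–80°) so angle-stream gaps track the
amplitude-proportional noise; gyro amplitude growing as 60·√A to limit
integration drift. Because noise is defined relative to amplitude, the
ladder spacing is precisely what makes the classes distinguishable at
all — with noise off, the model recovers every training instance's
movement; at the full 20% noise, stratified fivefold accuracy on the
900-instance protocol is 0.92 (seed 0; 0.92–0.95 across seeds).

What the generator does **not** emulate: biomechanics (stroke kinematics,
impact transients), sensor bias drift or clipping, inter-movement rest
gaps, or non-target daily-life movements. Passing tests therefore show
that the pipeline separates classes whose magnitude profiles are
distinct and periodic under heavy relative noise — not that it would
reach the same accuracy on real wrist recordings, where inter-class
differences are subtler and within-class variation is richer.

## Degenerate inputs and edge rules

* K-means requires k ≤ distinct points; layers 2 and 3 cap k at the
  number of distinct pooled vectors instead of failing (a constant
  stream fits with one effective cluster). Empty clusters re-seed to the
  farthest point; SSE is asserted non-increasing across every Lloyd
  iteration.
* A recording must produce at least 4 sub-feature points (≈ 50 samples)
  to be classifiable; shorter input raises a sizing error.
* Windows never extend past the stream; trailing partial windows are
  discarded. Buffer tails shorter than the median window merge into the
  previous buffer.
* The model file is versioned YAML (schema_version 1); loading restores
  bit-identical predictions, which the suite asserts.
* `k1 ≥ k2 ≥ 2` is validated at configuration time; the k₁ sweep caps
  k₂ at k₁.

## Known limitations

The single 1-D PCA scalar is the model's information bottleneck: classes
with identical magnitude profiles but different axis patterns are
indistinguishable by design (magnitudes are orientation-invariant).
Frequency-rank label space has no metric meaning, so Euclidean distances
between triples are only as good as the consistency of the ranking —
stable here because ranking is frequency-based and the fit is
permutation-stable, but sensitive to strong class imbalance. Restricting
the vocabulary to one sport raises that sport's mean recall, but not
necessarily every class's recall, since the restricted fit re-allocates
all 70 encode levels.
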