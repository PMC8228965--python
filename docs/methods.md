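# Methods

This note documents the models and procedures implemented in `collarml`,
the assumptions they make, and the choices taken where the design was
genuinely open.

## Label model

Annotations live on three channels per video: *valid* regions (the dog
fully visible and wearing the device), a *posture* channel that tiles
every valid instant with exactly one of six classes (LIE_DOWN, SIT,
STAND, WALK, VIGOROUS, MIXED — the catch-all), and a *behavior* channel
with zero or more simultaneous labels from nine active classes; NONE is
the implicit background and is materialized only at query time, never
stored. All intervals are half-open `[start, stop)`, so abutting
segments share no timepoint and posture tiling and transition detection
are unambiguous. Times are seconds relative to video start (double
precision); one absolute epoch is kept per track. Behavior segments may
cross valid/invalid boundaries; evaluation masks invalid regions anyway.

## Synthetic data generator

The generator stands in for private video-labeled datasets. It emulates
the features of real collar accelerometry that drive the pipeline's
difficulty, and nothing more:

* **Schedule.** An alternating background/active semi-Markov chain.
  Background (NONE) dwells are exponential with a 25 s mean; active
  bouts draw a behavior from a fixed NONE-dominant distribution (SNIFF
  and EAT common, SHAKE rare) and an exponential duration with
  per-class means set to the labeled-dataset values (DRINK 12.6 s, EAT
  43.4 s, SHAKE 1.7 s, ...). Exponential bouts reproduce the strong
  right skew of real label-length distributions; SHAKE instead uses a
  narrow gamma (shape 9), matching its short, uninterrupted character.
  Together these keep NONE above ~55% of labeled time and make EAT two
  orders of magnitude more prevalent than SHAKE.
* **Signal.** In a body frame with the x-axis along the neck:
  gravity `[sin φ, 0, cos φ]` with φ the neck pitch (posture baseline
  plus a behavior offset — head-down for eating/drinking/sniffing — and
  smoothed on a 150 ms scale), plus a band-limited motif oscillation per
  behavior (frequency, amplitude, burstiness), posture movement energy
  (WALK bobs at 2 Hz, VIGOROUS at 3 Hz), and white Gaussian noise
  (σ = 0.05 g; the choice is ours, no reference value exists). Motif
  frequencies stay below 6.25 Hz, the Nyquist limit of the slowest
  supported sampling rate (12.5 Hz).
* **Collar rotation.** A fixed per-recording rotation about the neck
  axis, applied to the complete body-frame signal (noise included), so
  the magnitude series is exactly rotation-invariant. Canonical
  positions: ventral 0°, right 90°, dorsal 180°, left 270°.
* **Clocks.** The device clock leads the video clock by a per-recording
  offset, uniform in [−5, +5] s by default.
* **Inter-individual variability.** Per-dog multiplicative jitter of
  motif frequency (log-σ 0.08) and amplitude (log-σ 0.18) and an
  additive pitch shift (σ 0.12 rad), making cross-dog generalization
  strictly harder than within-dog fitting. Setting `dog_jitter=0`
  removes it.
* **Defaults.** 25–50 Hz sampling enforced (default 32 Hz), 600 s
  videos, ~5% of each video carved into invalid regions.

What it does **not** model: wet-food and raised-bowl confounders, leash
artifacts, recording gaps by default, clock drift, or biomechanics
beyond what distinguishes classes. A high benchmark score therefore
shows that the pipeline's machinery is correct and that the designed
class structure is recoverable under fold hygiene, rotation, and clock
noise — not that real dogs would be classified with the same accuracy.
The motif parameters are free choices validated only by separability.

## Clock alignment

Device and video clocks disagree by seconds. The estimator computes a
movement-energy envelope (gravity removed with a ~0.5 Hz low-pass on the
magnitude, rectified, smoothed over 0.5 s, resampled to 10 Hz — the
manual peaks-to-labels matching made algorithmic), soft-saturates
it (`e/(e+0.1)`) so a single violent bout cannot dominate, and maximizes
Pearson correlation against a binary indicator of high-intensity labels
(SHAKE, SCRATCH behaviors; WALK, VIGOROUS postures) over ±30 s at 0.1 s
steps. Ties break toward the smallest |offset|; acceptance requires a
peak score of 0.3 and a unique peak (no rival within 0.01 more than 1 s
away). Tracks with under 2 s of high-intensity labels are rejected as
not alignable. The sync-shake detector finds the earliest envelope
excursion above 8× the median (with a 0.2 g absolute floor, so resting
traces never trigger). Non-constant offsets (drift) are out of scope.

On 100 seeded recordings with offsets uniform in [−5, 5] s, essentially
all accepted alignments land within ±0.25 s (the acceptance experiment
recomputes this).

## Dataset assembly

Entries are videos. Each dog is capped at 30 entries (uniform random
without replacement, seeded — the selection rule is otherwise arbitrary
and unspecified). Dogs are then packed into 5 folds greedy
largest-first by total valid-labeled duration; balancing by duration
rather than dog count stabilizes per-fold metric estimates.
Disjointness — all of a dog's videos in one fold — is guaranteed by
construction and asserted on every build. Summaries count labels and
durations over valid-region overlap only and render totals as H:MM:SS.

## Classifier

The classifier maps a recording to per-gridpoint distributions over
behaviors and postures on a fixed 320 ms grid. Input is linearly
resampled to 32 Hz (gaps over 2 s zero-filled with a mask channel).
Per-sample channels are all invariant to device rotation about the neck
axis: a ~0.5 Hz per-axis low-pass estimates the gravity vector, whose
neck-axis component is the pitch cue (the head-up/head-down signal that
distinguishes eating and drinking from background) and whose off-neck
norm is the complementary orientation cue; the per-axis high-pass
residual supplies its vector norm (dynamic energy), band energies
(0.5–1.5, 1.5–3, 3–6.5 Hz), and the zero-crossing rate of its neck-axis
component as a continuous dominant-frequency proxy. Windowed means
(plus stds of pitch and residual, plus observed-data fraction) are
pooled at three scales — 0.32 s, 1.28 s, 5.12 s — around each gridpoint,
giving a 5.12 s receptive field, and feed two standard-scaled MLP heads
(64→32 hidden units, Adam, seeded) — one per task, sharing the feature
trunk. Class imbalance is countered by inverse-frequency oversampling
capped at 20×. Multi-behavior timepoints are excluded from behavior
training, mirroring their exclusion from evaluation; MIXED postures are
kept as a training class because the model must produce a full posture
distribution (evaluation replaces MIXED predictions).

Training is per-fold: model *i* sees only dogs outside fold *i*;
cross-validated prediction gives every video exactly one prediction,
from the model that never saw its dog. Everything is deterministic
given config and seed. Desk-scale defaults (≤60 optimizer epochs,
CPU-only) are deliberate; reproducing production-scale accuracy on real
dogs is a non-goal.

## Evaluation protocol

Labels and predictions are paired at gridpoint centers and tallied into
per-task multiclass confusion matrices, pooled over videos and folds.
Exclusions: (a) invalid regions; (b) timepoints within 1 s of a class
transition on the task channel — with a 1/3 s margin on any side of a
boundary occupied by a lone SHAKE label, since a 1 s rule would erase
typical 1.7 s shake bouts entirely; valid-region edges count as
transitions, with the same class-resolved margins (a conservative
reading; the alternative of ignoring them is defensible too); (c)
behavior timepoints with more than one simultaneous label (NONE counts
as exactly one); (d) posture timepoints labeled MIXED. MIXED
*predictions* are replaced by the next most likely posture; exact
probability ties break to the lexicographically smaller class name.
One-vs-rest metrics derive from the stored counts bit-exactly, with
undefined ratios as NaN. Position breakdowns use a percentile bootstrap
(2000 resamples over videos, seeded) for 95% CIs on mean F1; positions
with fewer than two usable videos are flagged and get no CI.

## Event detection and validation analytics

Only the confidence score (mean per-gridpoint probability over the
event) and the 0.3 floor are fixed by the production description; the
segmentation itself is our reconstruction: hysteresis with enter 0.7 /
exit 0.5, closure after the probability stays below exit for more than
the merge gap (30 s), merging of segments separated by at most that
gap, and per-behavior minimum durations (60 s for EAT meals, 10 s for
DRINK). Validation analytics exclude "Not Sure" answers and responses
later than 60 min after the event's end; confidence bins are half-open
[0.3, 0.4) … with the top bin closed at 1.0.

## Problem sizes and numerical choices

The benchmark cohort is 40 dogs × 2 videos × 240 s (the cohort size
mirrors the separable-cohort experiment design; the video length is our
choice), the alignment experiment uses 100 recordings at the 600 s
default, and the position experiment re-records 12 base videos at the
four canonical positions (48 recordings), mirroring the four-device
study design. Grid counts use `ceil(duration / 0.32)` with a 1e-9 guard
against float edge cases; exclusion windows are open intervals; the
evaluation tally tolerates a one-gridpoint length difference between a
prediction and its track (rounding at trace edges) and rejects more as
structural error.

## Known limitations

Synthetic motifs are stationary sinusoid bursts, far simpler than real
dog movement; position invariance is exact by construction here (the
simulator rotates about the ideal neck axis and the features are exact
invariants), whereas on real hardware it is only approximate; the
alignment reconstruction assumes a constant offset; event segmentation
parameters are not validated against any production system; and the MLP
heads, while multi-scale in their temporal features, have no learned
convolutional structure.
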