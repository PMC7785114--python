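# Methods

`auda` assesses whether a smile is spontaneous or posed from the time
series of facial action-unit (AU) intensities that an AU detector (e.g.
OpenFace) extracts from video. This note documents the models, the
numerical choices, and what the synthetic test bed does and does not
show.

## Signal model and dynamics

The input is a sequence of 17 per-frame AU intensities (AU1, AU2, AU4,
AU5, AU6, AU7, AU9, AU10, AU12, AU14, AU15, AU17, AU20, AU23, AU25,
AU26, AU45), normalized from the detector's 0–5 regression scale to
[0, 1] by dividing by 5 and clipping. Out-of-range raw values are
clipped with a logged warning rather than rejected, since isolated
detector glitches should not void a whole sequence.

For any intensity signal v(t) we compute multi-scale dynamics:

* a 3-frame median filter removes single-frame spikes (edges
  replicated);
* a sliding window of ω consecutive frames (unit stride, centered on
  the output frame) is fitted by least squares, giving the slope
  δ_i = Σ(t−t̄)(v−v̄) / Σ(t−t̄)² in intensity/s and the correlation
  r_i = Σ(t−t̄)(v−v̄) / √(Σ(t−t̄)² Σ(v−v̄)²) ∈ [−1, 1];
* the r-adjusted slope δ̂_i = δ_i·|r_i| suppresses slopes from poorly
  linear windows;
* applying the slope pass to δ itself (without a second median filter)
  yields the second-order dynamics δ².

Boundary handling replicates the (t, v) *pair* at the edges. Replicated
points lie on the signal's own trend line, so a pure ramp keeps its
exact slope at every frame, including the first and last — a cleaner
invariant than timestamp extrapolation, which would flatten edge
slopes. A window that is constant up to floating-point rounding
(centered sum of squares below (10⁻¹³·max|v|)²·ω) is assigned δ = r = 0:
a constant window carries no trend evidence, and the threshold is far
below any physically meaningful intensity variation.

Window lengths are stated at a 50 fps reference rate; for other frame
rates the span (ω−1)/fps is preserved via
ω′ = 2·⌊(ω_ref−1)·fps/100⌋ + 1 (always odd, clamped to ≥ 3 with a
warning). At 50 fps, ω = 9, 15, 27 cover 160, 280 and 520 ms.

Slopes are computed against true timestamps, so irregular-but-monotone
time bases are handled; at exactly 50 fps this is identical to assuming
20 ms spacing.

## Smile intensity

A binary RBF-kernel SVM over the 17 AU intensities (standardized,
class-weighted, hyperparameters from a small grid C ∈ {0.1, 1, 10, 100},
γ ∈ {0.01, 0.1, 1} on a held-out fifth of the training frames) scores
each frame by its signed distance from the separating hyperplane. The
margin is divided by the 99th percentile of |margin| over the training
frames and clipped, mapping scores into [−1, 1] with 0 exactly on the
smile/non-smile boundary; the percentile (rather than the maximum) makes
the scale robust to outlier frames. Optional seeded undersampling of the
majority class addresses strongly imbalanced frame sets.

Downstream phase detection only uses relative changes and slope signs,
so when no trained frame classifier is available the pipeline accepts a
monotone surrogate; the default proxy is the mean of AU6 (cheek raiser)
and AU12 (lip corner puller), the two smile-defining channels.

## Phase segmentation

Segmentation runs on v, δ and δ² at ω = effective_window(27, fps) and
assumes nothing about the number of smiles in a sequence. Per event:

1. **Extent.** The event starts at the first frame with δ > 0. A scan
   then looks for the final descent while maintaining the running
   maximum v_max and the reference level v_ref = (v_on + v_max)/2,
   stopping when v falls below v_ref *and* δ < 0 (requiring a negative
   slope avoids stopping on incidental dips). The event ends at the
   next frame where δ ≥ 0, or at the end of the signal.
2. **Preliminary apex limits** are the frames of fastest increase
   (argmax δ) and fastest decrease (argmin δ) within the event.
3. **Fine-tuning.** The apex starts at the first and ends at the last
   strict 3-frame local minimum of δ² between those limits (maximum
   convexity of v); when no local minimum exists the preliminary limits
   are used. Plateaus in δ² take their first (apex start) / last (apex
   end) frame.

Candidates must satisfy t_on < t_ap ≤ t_off < t_end (with a fallback to
the preliminary limits before discarding) and last at least **1 second**;
shorter candidates are dropped and their frames remain "none". The
search resumes at the event's end, so any number of smiles is handled.
Phase ranges are half-open, 0-based: onset [t_on, t_ap), apex
[t_ap, t_off), offset [t_off, t_end).

The event-end test uses δ ≥ 0 rather than strictly positive. On noisy
real signals the two coincide; on an exactly flat baseline the slope
settles at exactly zero and a strict test would drag t_end to the end
of the recording, so the non-strict test is what makes detection
invariant to appending baseline frames — an invariant the test suite
checks.

Detected boundaries are blurred by up to about half a detection window
(≈ 260 ms at 50 fps): the centered window "sees" an approaching rise,
so onsets start early by up to ω/2 frames. This is inherent to the
method and bounded by the window span.

## Features

For every smile, features come from four ranges — the whole event and
its three phases — in two families, giving eight vectors:

* **AU-wise** (per channel): amplitude v_a = v_max − v_min, mean and
  maximum of the raw intensity, plus mean and maximum of δ at each
  scale ω ∈ Ω. For Ω = {9, 27}: 17·(3 + 2·2) = 119 features per range
  (51 of them ω-independent, 7 per AU).
* **Cross-AU** (per unordered pair): minimum and maximum of the
  dynamics difference δΔ = |δ_x − δ_y|, and the temporal distances (in
  seconds) between the two channels' δ̂ maxima and between their δ̂
  minima. 136 pairs × 4 = 544 features per scale (1088 for two scales).

Dynamics are computed once on the full sequence and then restricted to
each range; recomputing inside a range would inject replication
artifacts at phase borders. δΔ extrema use the unadjusted slopes; only
the temporal-distance features use δ̂. argmax/argmin ties take the
earliest frame. A phase shorter than two frames is computed on the
minimal 2-frame extension and flagged, keeping all vectors fixed-length.
Channels are processed in canonical AU order regardless of input
ordering, so named feature values are permutation-invariant. v_min is
not emitted on its own; it only enters through the amplitude.

## Classifier

Each of the eight vectors feeds its own first-level RBF-kernel SVM
after per-feature standardization (zero-variance features pass through
unscaled). Hyperparameters come from a grid search (C ∈ {0.1, 1, 10,
100}, γ ∈ {0.1, 1, 10}/d) on an internal validation split — 20% of the
training set, subject-disjoint when subject IDs are available, seeded.
The eight signed decision values are stacked into a second-level
polynomial-kernel SVM (degree 3); its training inputs are produced by
internal 5-fold cross-fitting rather than resubstitution, so the
stacker is trained on honestly out-of-fold margins. An optional ninth
first-level classifier accepts an externally supplied feature table.

Recursive feature elimination is available per slot: feature importance
is measured by leave-one-feature-out validation accuracy; per round the
least important max(1, 5% of remaining) features are removed and the
round is accepted iff validation accuracy does not decrease (ties
accepted), stopping at the first rejected round. Because the
leave-one-out importance requires one SVM fit per remaining feature per
round, RFE is quadratic in fits over the 1088-dimensional cross-AU
slots; it therefore defaults to off and is enabled with `--rfe` (the
planted-signal tests exercise it on small feature sets).

Evaluation is subject-disjoint k-fold cross-validation (shuffled,
seeded): folds partition the data, no subject appears on both sides of
a split, and standardization/grid search/RFE see only the training
folds. Accuracy (%) and ROC AUC (tie-aware pairwise probability) are
reported per fold and as mean ± sd. At prediction time every detected
smile is classified independently; a sequence-level label, when needed,
is that of the longest event, and a sequence with no detected event is
classified through a flagged fallback event spanning the whole sequence
with the apex covering its interior.

## Synthetic test bed

The generator emulates the study conditions at every level: labeled
smile/non-smile AU frames, single- and multi-event intensity profiles
with exact ground-truth breakpoints, and class-labeled AU sequences
with subject structure.

A smile profile is baseline + amplitude × (raised-cosine rise, plateau,
raised-cosine fall); linear ramps are available for analytic tests.
Segment frame counts are ⌊duration·fps⌋ (with a 10⁻⁹ s guard against
binary rounding). Defaults, chosen once as realistic for 50 fps smile
recordings: posed onset 0.6 s, apex 3.0 s, offset 1.2 s, amplitude
0.80 ± 0.05; spontaneous onset 0.9 s (1.5×), amplitude 0.56 (0.7×
posed); 10% relative jitter on phase durations; baseline 0.05 with
0.2 s lead-in and 0.1 s tail padding. Each AU channel is
gain·profile(t − lag) + baseline + noise clipped to [0, 1], with AU6 and
AU12 at gain 1.0, mouth-area AUs intermediate, the rest weakly coupled;
per-AU lags jitter by ±2 frames, and in the spontaneous class AU6 lags
AU12 by 3 frames. Independent Gaussian noise has sd 0.02 per channel
(or a stated SNR, defined as 10·log₁₀ of clean-signal variance over
noise variance). Subjects contribute two sequences each and carry a
small baseline shift (sd 0.03) so subject-disjoint folding is
meaningful.

What passing tests show — and don't. The generator produces smooth,
single-bump, near-trapezoid smiles with stationary noise and linearly
separable class effects; real smiles have irregular apex dynamics,
multiple partial peaks, detector dropouts and much weaker, non-additive
class differences. Classifier accuracies on the synthetic bed therefore
validate the machinery (no leakage, correct protocol, sane stacking),
not the accuracy attainable on real recordings.

Problem sizes used by the test suite and the acceptance script: the
classifier properties run on the generator's default study of n = 200
sequences (100 subjects) with 2-fold subject-disjoint cross-validation;
phase-robustness curves use 20 noise replicates per SNR level; the
duration-threshold sweep covers 0.5–1.5 s in 0.02 s steps.

## Known limitations

* Onset boundaries lead the true rise by up to half a detection window;
  no deblurring is attempted.
* The 1-second minimum duration is a hard threshold; smiles of
  borderline length flicker in and out of detection under noise.
* The [−1, 1] margin scaling depends on the training-frame margin
  distribution; scores from different trained frame classifiers are not
  comparable.
* RFE's leave-one-feature-out importance is expensive on the cross-AU
  slots; a coefficient-based screen would be faster but is a different
  algorithm and is deliberately not substituted.
* The reader for externally published feature tables supports this
  package's documented layout; mapping other columnar layouts onto the
  eight slots is left to a user-supplied column mapping.
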