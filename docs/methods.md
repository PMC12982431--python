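# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limitations of `neoeeg`. It complements the
README, which describes the user-facing pipeline.

## Pre-processing

The fixed chain is montage → filter → resample → segment → normalize.

* **Bipolar montage.** Derivations C3–C4, C3–Cz, C3–T4, C4–Cz, C4–T3,
  computed as `anode − cathode` in the referential domain so that any
  common recording reference cancels exactly. An electrode equal to the
  recording reference contributes the zero signal; missing electrodes
  are an error, never interpolated. T7/T8 are accepted as aliases of
  T3/T4 and label matching is case-insensitive.
* **Filtering.** 4th-order Butterworth band-pass 0.25–30 Hz applied
  forward–backward (`sosfiltfilt`). Zero phase matters because the
  artifact head emits per-sample masks that must stay aligned with the
  waveform. The band edges are fixed; the filter family and order are
  implementation choices. With an 8th-order effective response the
  transition band is gentle: a 45-Hz tone is attenuated below 10 % RMS,
  but content immediately above 30 Hz is only partially suppressed
  before the resampler's own anti-aliasing FIR removes it.
* **Resampling.** Polyphase (`resample_poly`) to 64 Hz; the rational
  factor is derived per input rate (e.g. 32/125 for 250 Hz). Input
  rates below 128 Hz are rejected — there is no reliable margin to
  band-limit at 30 Hz.
* **Segmentation.** Non-overlapping 30-s epochs of exactly 1920
  samples; the trailing partial epoch is discarded rather than padded so
  all segments are statistically comparable.
* **Normalization.** Per channel, every sample is divided by the median
  across segments of the per-segment SD. The median keeps the divisor
  insensitive to high-amplitude artifact segments; per-channel (rather
  than pooled) scope accommodates gain differences between derivations.
  Flat channels (median SD 0) are left unscaled and recorded in the
  metadata. Normalization is idempotent.

## The multi-task model

One shared, channel-agnostic encoder processes every derivation of every
segment identically; channel identity is never an input, which is what
lets one trained model run on 1–5 derivations without change. The
encoder is a deterministic 17-dimensional feature embedding per
channel-segment: the nine spectral features listed below, plus log SD,
the log–log spectral slope on 0.5–16 Hz, two envelope-modulation
descriptors from 3-s-window SDs (p90/p10 ratio and minimum-to-overall
ratio, which capture quiet-sleep discontinuity), relative 10–30 Hz
power, line length, kurtosis, and zero-crossing rate.

Four heads sit on this embedding:

* **FBA** — gradient-boosted regression (absolute-error loss) onto age
  in weeks.
* **Sleep** — gradient-boosted 3-class classification (QS, AS, wake);
  probabilities aligned to a fixed stage order, a stage absent from
  training receives probability zero.
* **Artifact** — a gradient-boosted classifier over 1-s windows of
  three amplitude features (log RMS, log peak, first-difference ratio);
  window probabilities are upsampled (nearest-neighbour) to 1920
  per-sample probabilities and thresholded at 0.5. Boosted trees are
  required here because artifact classes are non-monotone in amplitude:
  movement transients are high-RMS, disconnections near-zero.
* **Attention** — a gradient-boosted regressor predicting the FBA
  head's age accuracy for the channel-epoch, as `exp(−|residual| / 2
  weeks)`; the raw attention is `softplus(8·(score − 0.5))`, strictly
  positive and unbounded above so percentile calibration is meaningful.
  Channel-epochs whose spectral content misleads the age estimate
  (artifacts, novelties, idiosyncratic background) earn low attention,
  and the target is continuous, giving the calibrated threshold a
  distribution with genuine spread to sit on.

Training is multi-task over heterogeneously labeled recordings: each
head is fitted only where its label exists; a task with no labels is
dropped with a warning. Age and sleep heads train on clean channel-
epochs only (artifact overlap > 10 % or injected novelty excluded);
the artifact and attention heads see everything. All estimators are
seeded with early stopping on an internal validation split, so training
is exactly reproducible.

Aggregation uses linear normalization `w_i = a_i / Σ a_j` over included
channels (not a softmax): it preserves the raw attention scale that the
uncertainty criterion thresholds, keeps simplex vectors on the simplex,
and reduces to the identity for a single included channel. One attention
weight is shared by the sleep and FBA outputs.

## Quality control

Three independent criteria per segment; their OR is the reject flag.
Flags never modify predictions.

* **Artifact**: fraction of artifact-masked samples pooled over all
  channels `> 0.5`, strict. Pooling matches the segment-level nature of
  the flag.
* **Novelty**: per task, an isolation forest (100 trees, subsample 256,
  contamination 0.05, seeded) over nine spectral features per
  channel-segment — relative power in δ (0.5–3 Hz), θ (3–8), α (8–15),
  β (15–30); spectral edge frequencies at 75/90/95 % of total power;
  normalized spectral entropy; log total power — computed from a Welch
  periodogram (4-s windows, 50 % overlap) restricted to 0.5–30 Hz.
  This particular nine-feature set is a documented stand-in isolated
  behind one function. Novel channels get aggregation weight exactly 0;
  strictly more than half novel flags the segment. The forests are
  fitted on the features of each task's *training* recordings —
  including their routine artifact content — so ordinary artifacts stay
  in-distribution and novelty is reserved for genuinely alien signals
  (narrowband tones, white noise, ECG-like spike trains in the
  generator). Fitting them on pristine data instead makes the novelty
  criterion shadow the artifact criterion.
* **Uncertainty**: the maximum unnormalized attention over included
  channels falls below a threshold fixed at calibration time as the 1st
  percentile (type-7, linear interpolation) of per-segment maxima on an
  independent calibration set; for the sleep task, an aggregated QS
  probability within 0.1 of 0.5 also flags. The calibration set must be
  drawn from the same conditions as deployment data — with routine
  artifact content — otherwise the threshold sits unrealistically high
  and the uncertainty criterion dominates artifact-heavy recordings.
  One threshold is calibrated per task bundle.

Degenerate corner: if novelty excludes every channel, the segment is
flagged novelty-rejected and the unexcluded aggregate is kept for
inspection only.

## Outputs

* **Global FBA**: median of retained per-segment estimates; IQR (type-7
  quantiles) of the retained estimates as confidence; zero retained
  segments is an explicit no-estimate error.
* **Hypnogram**: QS iff smoothed `p_QS > 0.5`. Smoothing is a centered
  5-segment moving average over reliable segments only (kernel
  renormalized, truncated edges). Flagged runs of ≤ 4 segments (2 min)
  take the stage of agreeing flanking reliable segments; an
  artifact-flagged segment whose pooled RMS exceeds 3× the recording's
  median segment RMS and whose nearest reliable neighbours have mean
  wake probability > 0.5 is retained as non-QS ("wake-retained") —
  vigorous movement during wake is expected, not a reason to discard
  the stage. Everything else stays unreliable and carries no stage
  claim. Window and gap lengths are config-exposed defaults.
* **FBA trajectory**: rolling median of retained estimates (default
  60-min centered window, minimum 10 retained segments per window).

## Evaluation

* Absolute FBA error `|FBA − PMA|`; IQR coverage (PMA within the
  retained per-segment IQR, undefined below 4 retained segments).
* Cohen's kappa for QS vs non-QS with unreliable segments excluded;
  degenerate marginals (expected agreement 1) are defined as 1.0 for
  perfect agreement, else 0.0, with a warning.
* The duration-subsampling experiment draws contiguous windows with
  uniformly random onsets (overlap allowed) on a grid from 30 s to 1 h;
  naive = median of all segment predictions in the window, robust =
  median of retained only, computed on identical draws (paired design).
  Windows retaining zero segments are excluded from robust summaries
  and reported as a no-estimate rate. The robust x-axis convention
  counts retained data only.
* Per-channel evaluation re-runs aggregation restricted to each single
  derivation from the stored per-channel outputs.

## Synthetic study conditions

The generator's defaults define the study conditions; everything is
config-overridable and driven by one seed.

* Background: per channel, noise with PSD ∝ 1/f^β on 0.3–30 Hz,
  β = 2.4 − 0.05·(PMA − 27), so the spectral slope flattens
  monotonically from 27 to 47 weeks — the signal that makes brain age
  recoverable. Inter-channel correlation 0.3 via a shared source;
  amplitudes scaled to ~15 µV SD (≈ 30–120 µV peak-to-peak).
* Sleep architecture: alternating AS/QS bouts with lognormal durations
  (medians 20/15 min, σ_log 0.4), wake interruptions with exponential
  inter-arrival (median 90 min) and lognormal duration (median 5 min);
  bouts rounded to whole 30-s epochs, minimum 2 epochs.
* Stage signatures: QS amplitude alternates 6-s bursts with
  inter-burst troughs (gain 0.25) whose duration
  `max(2, 14 − 0.4·(PMA − 27))` s shrinks with maturation — a 50 % duty
  cycle near term, mimicking tracé alternant; AS is continuous at 0.8×;
  wake is continuous at 1.1× with +50 % relative 10–30 Hz power.
* Artifacts: epochs are selected binomially at `artifact_rate` (wake
  epochs draw additional movement events at the same rate, making
  movement twice as likely during wake); each selected epoch hosts one
  event placed fully inside its contiguous selected run, so the
  affected-epoch fraction tracks the configured rate. Families:
  movement (5–60 s, 5–15× amplitude, < 5 Hz, on 1..all channels),
  electrode pop (step + exponential decay, single channel), and
  flat/disconnection (10–120 s, whole montage — a single flat
  referential electrode would be invisible after bipolar derivation).
  The mask covers exactly the modified samples.
* Novelties: channel-epochs replaced at `novelty_rate` by a
  20-Hz-dominant narrowband tone, white noise, or a 2.2-Hz ECG-like
  spike train — all spectrally alien to the 1/f family.

What the generator does **not** emulate: real electrode physics,
seizures or abnormal background (the target population is neurologically
normal), inter-rater annotation noise, age-dependent sleep-architecture
changes, and the true covariance structure of clinical artifacts.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and self-consistent under known ground truth — not clinical
performance.

## Problem sizes and numerical choices

The study-scale runs train on 40 recordings (PMA 28–44, 60 min each,
artifact rate 0.2, novelty rate 0.02), calibrate on 6 independent
recordings of the same character, and evaluate 10 held-out recordings;
the duration experiment uses 20 recordings of 180 min with artifact rate
0.3 and 200 repetitions per duration. These sizes recover age with a
held-out MAE of ~0.3 weeks and QS kappa ~0.99 while keeping a full
from-scratch run in the minutes range on one CPU.

Quantile convention is type-7 (linear interpolation) throughout. EDF
fixtures are 16-bit with a symmetric physical range per channel, so
round-trip error is bounded by range/2¹⁵; reference electrodes are
encoded as a uniform `-<ref>` label suffix, the common clinical export
convention. All randomness flows from explicit seeds; repeated runs are
byte-identical including serialized result files (sorted JSON keys,
default float repr).

## Known limitations

* The encoder is a fixed feature embedding, not a learned
  representation; it is sufficient for the synthetic study conditions
  but would need replacing with a trainable encoder for clinical data.
* The nine novelty features and all postprocessing windows are
  documented defaults, each isolated behind one function/config knob.
* Flat single-electrode faults are undetectable downstream of the
  bipolar montage by construction; only whole-montage dropouts are
  modelled.
* Kappa confidence intervals and cross-center statistics are out of
  scope.
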