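"""Three independent per-segment reliability criteria.

1. **Artifact content** — the fraction of samples the artifact head marks
   as noise, pooled over channels; a segment with more than 50 % artifact
   content is flagged (brain activity is largely obscured).
2. **Novelty detection** — an isolation forest over nine spectral features
   decides, per channel and segment, inlier vs out-of-distribution. Novel
   channels are excluded from attention aggregation; when strictly more
   than half the channels are novel the whole segment is flagged. One
   forest is fitted per task from that task's training data.
3. **Uncertainty** — a segment whose maximum unnormalized attention weight
   over channels falls below a calibrated threshold (the 1st percentile of
   maxima on an independent calibration set) is flagged; for the sleep
   task, segments with an aggregated QS probability near 0.5 are flagged
   as well.

Flags never modify predictions; downstream, FBA excludes flagged segments
and sleep staging marks them for heuristic interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import IsolationForest
from sklearn.preprocessing import StandardScaler

from neoeeg.errors import CalibrationError
from neoeeg.features import (  # noqa: F401  (re-exported public surface)
    SPECTRAL_FEATURE_NAMES,
    spectral_features,
    spectral_features_batch,
)

MIN_NOVELTY_FIT_SAMPLES = 500
MIN_CALIBRATION_SEGMENTS = 100


@dataclass
class QCThresholds:
    """Decision thresholds for the three criteria.

    ``attention_min`` must come from :func:`calibrate_attention_threshold`;
    the other values are fixed pipeline constants.
    """

    artifact_fraction_max: float = 0.5
    novelty_channel_fraction: float = 0.5  # strictly-more-than rule
    attention_min: float | None = None
    qs_uncertainty_halfwidth: float = 0.1


@dataclass
class SegmentFlags:
    """Per-segment quality-control verdicts; ``reject`` is their OR."""

    artifact: bool
    novelty: bool
    uncertain: bool
    channel_novelty: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    reject: bool = False

    def __post_init__(self):
        self.reject = bool(self.artifact or self.novelty or self.uncertain)


def artifact_fraction(masks: np.ndarray) -> float:
    """Fraction of artifact samples pooled over all channels of a segment."""
    masks = np.atleast_2d(np.asarray(masks, dtype=bool))
    return float(masks.mean())


def flag_artifact(fraction: float, thresholds: QCThresholds) -> bool:
    """True iff artifact content strictly exceeds 50 %."""
    return fraction > thresholds.artifact_fraction_max


@dataclass
class NoveltyModel:
    """Fitted isolation forest + feature standardization, per task."""

    forest: IsolationForest
    task: str
    feature_mean: np.ndarray
    feature_sd: np.ndarray

    def decision(self, features: np.ndarray) -> np.ndarray:
        z = (np.atleast_2d(features) - self.feature_mean) / self.feature_sd
        return self.forest.predict(z) == -1


def fit_novelty_model(
    features: np.ndarray,
    task: str,
    seed: int = 0,
    n_trees: int = 100,
    subsample: int = 256,
    contamination: float = 0.05,
) -> NoveltyModel:
    """Fit an isolation forest on inlier spectral features for one task."""
    features = np.asarray(features, dtype=float)
    if len(features) < MIN_NOVELTY_FIT_SAMPLES:
        raise CalibrationError(
            f"need >= {MIN_NOVELTY_FIT_SAMPLES} inlier channel-segments, "
            f"got {len(features)}"
        )
    scaler = StandardScaler().fit(features)
    sd = np.where(scaler.scale_ == 0, 1.0, scaler.scale_)
    forest = IsolationForest(
        n_estimators=n_trees,
        max_samples=min(subsample, len(features)),
        contamination=contamination,
        random_state=seed,
    )
    forest.fit((features - scaler.mean_) / sd)
    return NoveltyModel(forest=forest, task=task, feature_mean=scaler.mean_, feature_sd=sd)


def majority_novelty(channel_flags: np.ndarray) -> bool:
    """Segment-level rule: strictly more than half the channels novel."""
    flags = np.asarray(channel_flags, dtype=bool)
    return bool(flags.sum() > flags.size / 2.0)


def detect_novelties(model: NoveltyModel, features: np.ndarray):
    """Per-channel novelty flags and the segment-level majority flag.

    ``features`` is (n_channels, 9). Channels flagged novel are to be
    excluded from aggregation even when the segment as a whole is kept.
    """
    channel_flags = model.decision(features)
    return channel_flags, majority_novelty(channel_flags)


def calibrate_attention_threshold(max_attentions) -> float:
    """1st percentile (linear-interpolation) of per-segment attention maxima."""
    vals = np.asarray(max_attentions, dtype=float)
    if vals.size < MIN_CALIBRATION_SEGMENTS:
        raise CalibrationError(
            f"need >= {MIN_CALIBRATION_SEGMENTS} calibration segments, got {vals.size}"
        )
    return float(np.percentile(vals, 1.0))


def flag_uncertain(
    max_attention_raw: float,
    qs_prob: float | None,
    thresholds: QCThresholds,
    task: str,
) -> bool:
    """Attention below the calibrated floor, or (sleep) QS probability near 0.5."""
    if thresholds.attention_min is None:
        raise CalibrationError("attention threshold not calibrated")
    if max_attention_raw < thresholds.attention_min:
        return True
    if task == "sleep" and qs_prob is not None:
        return abs(qs_prob - 0.5) <= thresholds.qs_uncertainty_halfwidth
    return False


def combine_flags(
    artifact: bool,
    novelty: bool,
    uncertain: bool,
    channel_novelty: np.ndarray | None = None,
) -> SegmentFlags:
    """Bundle the three independent criteria; ``reject`` is their OR."""
    return SegmentFlags(
        artifact=bool(artifact),
        novelty=bool(novelty),
        uncertain=bool(uncertain),
        channel_novelty=(
            np.zeros(0, bool) if channel_novelty is None else np.asarray(channel_novelty)
        ),
    )
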