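"""End-to-end analysis: preprocessing -> model -> QC -> robust outputs.

A :class:`ModelBundle` holds everything an analysis run needs — the
trained multi-task model, one fitted novelty detector per task, one
calibrated attention threshold per task and the fixed QC thresholds — so a
run is fully reproducible from a single file. Analysis refuses to run on
an uncalibrated bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from neoeeg import eeg_io, postprocess, quality_control as qc
from neoeeg.eeg_io import DEFAULT_PAIRS, RawRecording, SegmentArray
from neoeeg.errors import CalibrationError, InsufficientDataError
from neoeeg.model import NeonatalModel, TrainingExample, aggregate
from neoeeg.postprocess import FBAResult, Hypnogram, HypnogramConfig

logger = logging.getLogger(__name__)

TASKS = ("fba", "sleep")


@dataclass
class ModelBundle:
    """Trained model + calibration artifacts, serialized as one unit."""

    model: NeonatalModel
    novelty_models: dict = field(default_factory=dict)  # task -> NoveltyModel
    attention_thresholds: dict = field(default_factory=dict)  # task -> float
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    hypnogram_config: HypnogramConfig = field(default_factory=HypnogramConfig)
    pairs: tuple = DEFAULT_PAIRS
    meta: dict = field(default_factory=dict)

    @property
    def calibrated(self) -> bool:
        return all(t in self.novelty_models for t in TASKS) and all(
            t in self.attention_thresholds for t in TASKS
        )

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ModelBundle":
        import joblib

        bundle = joblib.load(path)
        if not isinstance(bundle, ModelBundle):
            raise CalibrationError(f"{path} is not a model bundle")
        return bundle


def prepare_segments(rec: RawRecording, pairs=DEFAULT_PAIRS) -> SegmentArray:
    """Montage -> band-pass/resample -> segment -> normalize."""
    bp = eeg_io.derive_bipolar(rec, pairs)
    pp = eeg_io.preprocess(bp)
    return eeg_io.normalize(eeg_io.segment(pp))


def prepare_training_example(rec, truth, pairs=DEFAULT_PAIRS) -> TrainingExample:
    """Turn a generated recording + ground truth into a training example.

    Channel-epochs touched by injected artifacts (> 10 % of samples) or
    novelties are excluded from the age/sleep fits; the artifact head and
    the attention target see everything.
    """
    from neoeeg import synthetic_data

    segs = prepare_segments(rec, pairs)
    n_seg = segs.n_segments
    art64, nov = synthetic_data.derivation_masks(
        truth, rec.channel_labels, rec.reference_label, pairs, rec.fs
    )
    spe = segs.data.shape[-1]
    frac = art64[:, : n_seg * spe].reshape(len(pairs), n_seg, spe).mean(axis=-1)
    exclude = (frac > 0.1) | nov[:, :n_seg]
    return TrainingExample(
        segments=segs,
        age_weeks=truth.pma_weeks,
        hypnogram=truth.hypnogram[:n_seg],
        artifact_mask=art64,
        exclude_epochs=exclude,
    )


def task_inlier_features(examples) -> dict:
    """Spectral features of the channel-epochs in each task's training data.

    The novelty detectors are fitted per task on the data that trained that
    task's head — including the routine artifact content of those
    recordings — so ordinary artifacts stay in-distribution and the novelty
    criterion is reserved for genuinely alien signals.
    """
    feats = {t: [] for t in TASKS}
    for ex in examples:
        segs = ex.segments
        if segs.n_segments == 0:
            continue
        x = segs.data.transpose(1, 0, 2).reshape(-1, segs.data.shape[-1])
        f, _ = qc.spectral_features_batch(x, segs.fs)
        if ex.age_weeks is not None:
            feats["fba"].append(f)
        if ex.hypnogram is not None:
            feats["sleep"].append(f)
    return {t: np.vstack(v) for t, v in feats.items() if v}


def calibrate(
    bundle: ModelBundle, recordings, seed: int = 0, task_features: dict | None = None
) -> ModelBundle:
    """Fit novelty models and attention thresholds.

    ``recordings`` is an independent calibration set of
    :class:`RawRecording` whose per-segment maxima of the raw attention
    weights set the per-task uncertainty thresholds (1st percentile).
    ``task_features`` maps task name to the inlier spectral-feature matrix
    for that task's novelty forest (see :func:`task_inlier_features`); when
    omitted, the calibration recordings' own features are used for every
    task.
    """
    feats = []
    max_atts = []
    for rec in recordings:
        segs = prepare_segments(rec, bundle.pairs)
        if segs.n_segments == 0:
            continue
        x = segs.data.transpose(1, 0, 2).reshape(-1, segs.data.shape[-1])
        f, _ = qc.spectral_features_batch(x, segs.fs)
        feats.append(f)
        _, aggregated = bundle.model.predict_recording(segs)
        max_atts.extend(a.max_attention_raw for a in aggregated)
    if not feats:
        raise CalibrationError("no calibration segments")
    fallback = np.vstack(feats)
    for i, task in enumerate(TASKS):
        inliers = fallback if task_features is None else task_features.get(task, fallback)
        bundle.novelty_models[task] = qc.fit_novelty_model(
            inliers, task=task, seed=seed + i
        )
        bundle.attention_thresholds[task] = qc.calibrate_attention_threshold(max_atts)
    bundle.meta["calibration_segments"] = int(len(max_atts))
    return bundle


@dataclass
class AnalysisResult:
    """Everything one recording's analysis produced."""

    n_segments: int
    start_times: np.ndarray
    channel_labels: list
    channel_outputs: list  # per segment: list of ChannelOutputs
    aggregated: list  # per segment: AggregatedOutputs (novelty-excluded)
    flags: dict  # task -> list of SegmentFlags
    fba: FBAResult | None
    hypnogram: Hypnogram | None
    trajectory: tuple | None  # (times_s, values)
    qc_summary: dict
    segment_rms: np.ndarray


def _segment_flags(bundle, task, art_frac, channel_novel, max_att, qs_prob):
    thr = qc.QCThresholds(
        artifact_fraction_max=bundle.qc_thresholds.artifact_fraction_max,
        novelty_channel_fraction=bundle.qc_thresholds.novelty_channel_fraction,
        attention_min=bundle.attention_thresholds[task],
        qs_uncertainty_halfwidth=bundle.qc_thresholds.qs_uncertainty_halfwidth,
    )
    artifact = qc.flag_artifact(art_frac, thr)
    novelty = qc.majority_novelty(channel_novel)
    uncertain = qc.flag_uncertain(
        max_att, qs_prob if task == "sleep" else None, thr, task
    )
    return qc.combine_flags(artifact, novelty, uncertain, channel_novel)


def analyze(bundle: ModelBundle, rec: RawRecording, trajectory_minutes: float = 60.0):
    """Run the full pipeline on one recording.

    Per segment: per-channel predictions, novelty detection (novel
    channels excluded, then re-aggregation), the three QC criteria per
    task; then the robust global FBA (flagged segments excluded) and the
    postprocessed hypnogram (flagged segments interpolated/retained).
    """
    if not bundle.calibrated:
        raise CalibrationError("bundle is not calibrated; run calibrate first")
    segs = prepare_segments(rec, bundle.pairs)
    n_seg, n_ch = segs.n_segments, segs.n_channels
    if n_seg == 0:
        return AnalysisResult(
            0, segs.start_times, segs.channel_labels, [], [], {t: [] for t in TASKS},
            None, None, None, {"n_segments": 0}, np.zeros(0),
        )

    channel_outputs, _ = bundle.model.predict_recording(segs)
    x = segs.data.transpose(1, 0, 2)  # (n_seg, n_ch, 1920)
    feats, _ = qc.spectral_features_batch(
        x.reshape(-1, x.shape[-1]), segs.fs
    )
    feats = feats.reshape(n_seg, n_ch, -1)
    segment_rms = np.sqrt((x**2).mean(axis=(1, 2)))

    aggregated = []
    flags = {t: [] for t in TASKS}
    channel_novel_by_task = {
        t: bundle.novelty_models[t].decision(feats.reshape(-1, feats.shape[-1])).reshape(
            n_seg, n_ch
        )
        for t in TASKS
    }
    for s in range(n_seg):
        outs = channel_outputs[s]
        # exclusion uses the sleep-task detector's verdict for aggregation
        # (one aggregation feeds both outputs; the detectors share data and
        # in practice agree) but each task's flag uses its own detector
        novel = channel_novel_by_task["fba"][s]
        if novel.all():
            agg = aggregate(outs)  # informational only; segment is flagged
        else:
            agg = aggregate(outs, excluded=novel)
        aggregated.append(agg)
        art_frac = qc.artifact_fraction(
            np.asarray([o.artifact_mask for o in outs])
        )
        for task in TASKS:
            ch_novel = channel_novel_by_task[task][s]
            flags[task].append(
                _segment_flags(
                    bundle,
                    task,
                    art_frac,
                    ch_novel,
                    agg.max_attention_raw,
                    float(agg.sleep_probs[0]),
                )
            )

    fba_vals = np.asarray([a.fba_weeks for a in aggregated])
    try:
        fba_result = postprocess.global_fba(fba_vals, flags["fba"])
    except InsufficientDataError:
        fba_result = None
    probs = np.asarray([a.sleep_probs for a in aggregated])
    hyp = postprocess.build_hypnogram(
        probs, flags["sleep"], segment_rms, bundle.hypnogram_config
    )
    traj = None
    if n_seg * 0.5 >= trajectory_minutes / 2:
        traj = postprocess.fba_trajectory(fba_vals, flags["fba"], trajectory_minutes)

    summary = {"n_segments": int(n_seg)}
    for task in TASKS:
        fl = flags[task]
        summary[task] = {
            "artifact_fraction": float(np.mean([f.artifact for f in fl])),
            "novelty_fraction": float(np.mean([f.novelty for f in fl])),
            "uncertain_fraction": float(np.mean([f.uncertain for f in fl])),
            "rejected_fraction": float(np.mean([f.reject for f in fl])),
        }
    if hyp is not None:
        counts = {
            p: int(sum(1 for q in hyp.provenance if q == p))
            for p in ("model", "interpolated", "wake-retained", "unreliable")
        }
        summary["hypnogram_provenance"] = counts

    return AnalysisResult(
        n_segments=n_seg,
        start_times=segs.start_times,
        channel_labels=segs.channel_labels,
        channel_outputs=channel_outputs,
        aggregated=aggregated,
        flags=flags,
        fba=fba_result,
        hypnogram=hyp,
        trajectory=traj,
        qc_summary=summary,
        segment_rms=segment_rms,
    )


def write_results(result: AnalysisResult, outdir) -> None:
    """Write fba.json, hypnogram.csv, qc_summary.json, fba_trajectory.csv.

    Serialization is deterministic (sorted keys, repr floats), so repeated
    runs with identical inputs produce byte-identical files.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if result.fba is not None:
        fba_payload = {
            "fba_weeks": result.fba.fba_weeks,
            "iqr_q1_weeks": result.fba.iqr_weeks[0],
            "iqr_q3_weeks": result.fba.iqr_weeks[1],
            "n_retained": result.fba.n_retained,
            "n_total": result.fba.n_total,
            "retained_minutes": result.fba.retained_minutes,
        }
    else:
        fba_payload = {"error": "insufficient reliable data"}
    with open(outdir / "fba.json", "w") as fh:
        json.dump(fba_payload, fh, indent=2, sort_keys=True)

    if result.hypnogram is not None:
        hyp = result.hypnogram
        pd.DataFrame(
            {
                "epoch_index": np.arange(result.n_segments),
                "onset_s": result.start_times,
                "stage": [s if s is not None else "" for s in hyp.stages],
                "p_qs": hyp.p_qs,
                "provenance": hyp.provenance,
            }
        ).to_csv(outdir / "hypnogram.csv", index=False)

    with open(outdir / "qc_summary.json", "w") as fh:
        json.dump(result.qc_summary, fh, indent=2, sort_keys=True)

    if result.trajectory is not None:
        times, vals = result.trajectory
        pd.DataFrame({"time_s": times, "fba_weeks": vals}).to_csv(
            outdir / "fba_trajectory.csv", index=False
        )
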