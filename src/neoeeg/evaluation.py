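"""Performance metrics and the naive-vs-robust validation experiments.

* absolute FBA error against postmenstrual age, and whether the true PMA
  falls inside the IQR of the retained per-segment estimates;
* Cohen's kappa for quiet-sleep detection (QS vs non-QS), with unreliable
  segments excluded;
* the duration-subsampling experiment: contiguous sub-epochs of growing
  length are drawn at random positions, and the naive estimate (median of
  all segment predictions in the window) is compared against the robust
  one (median of quality-control-retained predictions only) on identical
  draws — a paired design, so any difference is attributable to rejection;
* per-channel evaluation: the same metrics recomputed with aggregation
  restricted to each single derivation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from neoeeg import postprocess
from neoeeg.errors import InsufficientDataError
from neoeeg.model import aggregate
from neoeeg.pipeline import AnalysisResult, ModelBundle, analyze

logger = logging.getLogger(__name__)

#: sub-epoch duration grid, seconds (30 s .. 1 h)
DEFAULT_DURATIONS_S = (30, 60, 120, 300, 600, 1200, 1800, 3600)


def absolute_error(fba_weeks: float, pma_weeks: float) -> float:
    """Absolute difference between the global FBA estimate and the PMA."""
    return abs(float(fba_weeks) - float(pma_weeks))


def cohen_kappa(pred, ref, exclude=None) -> float:
    """Chance-corrected agreement between two binary label sequences.

    ``exclude`` masks segments to drop (e.g. flagged unreliable). With
    degenerate marginals (expected agreement 1), kappa is defined as 1.0
    for perfect agreement and 0.0 otherwise, with a warning.
    """
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError("pred and ref must have equal length")
    keep = np.ones(len(pred), dtype=bool) if exclude is None else ~np.asarray(exclude)
    p, r = pred[keep], ref[keep]
    if len(p) < 2:
        raise ValueError("need >= 2 non-excluded segments")
    classes = np.unique(np.concatenate([p, r]))
    n = len(p)
    p_o = float(np.mean(p == r))
    p_e = float(
        sum((np.mean(p == c)) * (np.mean(r == c)) for c in classes)
    )
    if p_e >= 1.0 - 1e-12:
        warnings.warn("degenerate marginals in cohen_kappa; returning 1.0/0.0")
        return 1.0 if p_o >= 1.0 - 1e-12 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def iqr_coverage(fba_per_segment_retained, pma_weeks: float):
    """True iff the PMA lies within the IQR of the retained estimates.

    Returns None (reported as missing) with fewer than 4 retained
    segments, where the quartiles are too unstable to interpret.
    """
    vals = np.asarray(fba_per_segment_retained, dtype=float)
    if vals.size < 4:
        return None
    q1, q3 = np.percentile(vals, [25.0, 75.0])
    return bool(q1 <= pma_weeks <= q3)


@dataclass
class DurationCurve:
    """Summaries of the duration-subsampling experiment.

    For each duration and method: median/min/max absolute error over
    repetitions and the median IQR width of the per-segment estimates in
    the window. Robust windows that retain zero segments produce no
    estimate; their rate is reported separately. ``median_retained_s``
    gives the robust x-axis convention (duration of non-rejected data).
    """

    durations_s: np.ndarray
    n_rep: int
    seed: int
    naive: dict = field(default_factory=dict)
    robust: dict = field(default_factory=dict)
    no_estimate_rate: np.ndarray | None = None
    median_retained_s: np.ndarray | None = None


def duration_subsample_experiment(
    fba_per_segment,
    flags,
    pma_weeks: float,
    durations_s=DEFAULT_DURATIONS_S,
    n_rep: int = 1000,
    seed: int = 0,
) -> DurationCurve:
    """Paired naive-vs-robust evaluation over random contiguous sub-epochs.

    For each duration, ``n_rep`` window onsets are drawn uniformly (with
    possible overlap); the naive estimate is the median over all segment
    predictions in the window, the robust one the median over retained
    predictions only — computed on the same draws.
    """
    vals = np.asarray(fba_per_segment, dtype=float)
    reject = np.asarray([bool(f.reject) for f in flags])
    n = len(vals)
    rng = np.random.default_rng(seed)

    used = []
    naive_stats = {"median": [], "min": [], "max": [], "median_iqr": []}
    robust_stats = {"median": [], "min": [], "max": [], "median_iqr": []}
    no_est = []
    med_retained = []
    for dur in durations_s:
        length = int(dur // 30)
        if length < 1 or length > n:
            logger.warning("duration %ss exceeds recording; skipped", dur)
            continue
        used.append(dur)
        starts = rng.integers(0, n - length + 1, size=n_rep)
        naive_err = np.empty(n_rep)
        naive_iqr = np.empty(n_rep)
        robust_err = np.full(n_rep, np.nan)
        robust_iqr = np.full(n_rep, np.nan)
        retained_counts = np.zeros(n_rep)
        for k, s in enumerate(starts):
            w = vals[s : s + length]
            keep = ~reject[s : s + length]
            naive_err[k] = abs(np.median(w) - pma_weeks)
            q1, q3 = np.percentile(w, [25.0, 75.0])
            naive_iqr[k] = q3 - q1
            retained_counts[k] = keep.sum()
            if keep.any():
                r = w[keep]
                robust_err[k] = abs(np.median(r) - pma_weeks)
                q1, q3 = np.percentile(r, [25.0, 75.0])
                robust_iqr[k] = q3 - q1
        ok = np.isfinite(robust_err)
        no_est.append(float(1.0 - ok.mean()))
        med_retained.append(float(np.median(retained_counts) * 30.0))
        naive_stats["median"].append(float(np.median(naive_err)))
        naive_stats["min"].append(float(naive_err.min()))
        naive_stats["max"].append(float(naive_err.max()))
        naive_stats["median_iqr"].append(float(np.median(naive_iqr)))
        robust_stats["median"].append(float(np.median(robust_err[ok])) if ok.any() else np.nan)
        robust_stats["min"].append(float(robust_err[ok].min()) if ok.any() else np.nan)
        robust_stats["max"].append(float(robust_err[ok].max()) if ok.any() else np.nan)
        robust_stats["median_iqr"].append(
            float(np.nanmedian(robust_iqr[ok])) if ok.any() else np.nan
        )

    return DurationCurve(
        durations_s=np.asarray(used, dtype=float),
        n_rep=n_rep,
        seed=seed,
        naive={k: np.asarray(v) for k, v in naive_stats.items()},
        robust={k: np.asarray(v) for k, v in robust_stats.items()},
        no_estimate_rate=np.asarray(no_est),
        median_retained_s=np.asarray(med_retained),
    )


@dataclass
class MetricsReport:
    """Per-recording evaluation against ground truth."""

    abs_fba_error_weeks: float | None
    kappa_qs: float | None
    pma_in_iqr: bool | None
    per_channel: dict  # derivation label (and "all") -> metrics dict
    rejection_fractions: dict


def _stage_to_binary(stages):
    """QS vs non-QS; wake and AS collapse into the non-QS class."""
    return np.asarray([1 if s == "QS" else 0 for s in stages])


def _metrics_from_result(
    result: AnalysisResult, pma_weeks, ref_hypnogram
):
    out = {}
    fba_vals = np.asarray([a.fba_weeks for a in result.aggregated])
    reject = np.asarray([f.reject for f in result.flags["fba"]])
    if pma_weeks is not None and result.fba is not None:
        out["abs_fba_error_weeks"] = absolute_error(result.fba.fba_weeks, pma_weeks)
        out["pma_in_iqr"] = iqr_coverage(fba_vals[~reject], pma_weeks)
    else:
        out["abs_fba_error_weeks"] = None
        out["pma_in_iqr"] = None
    if ref_hypnogram is not None and result.hypnogram is not None:
        hyp = result.hypnogram
        scored = np.asarray([s is not None for s in hyp.stages])
        ref = _stage_to_binary(ref_hypnogram[: result.n_segments])
        pred = np.asarray([1 if s == "QS" else 0 for s in hyp.stages])
        if scored.sum() >= 2:
            out["kappa_qs"] = cohen_kappa(pred, ref, exclude=~scored)
        else:
            out["kappa_qs"] = None
    else:
        out["kappa_qs"] = None
    return out


def evaluate_recording(
    bundle: ModelBundle,
    rec,
    pma_weeks: float | None = None,
    ref_hypnogram=None,
) -> MetricsReport:
    """Full-pipeline evaluation of one recording.

    Headline metrics use the attention-weighted aggregate over all
    included channels; ``per_channel`` additionally re-runs aggregation
    restricted to each single derivation (the aggregated entry is stored
    under ``"all"``). Rejection fractions per criterion are reported per
    task; the criteria are not mutually exclusive, so they may sum to more
    than the overall rejection fraction.
    """
    if pma_weeks is None:
        pma_weeks = rec.meta.get("pma_weeks")
    result = analyze(bundle, rec)
    headline = _metrics_from_result(result, pma_weeks, ref_hypnogram)

    per_channel = {"all": headline}
    for c, label in enumerate(result.channel_labels):
        single = _single_channel_result(bundle, result, c)
        per_channel[label] = _metrics_from_result(single, pma_weeks, ref_hypnogram)

    return MetricsReport(
        abs_fba_error_weeks=headline["abs_fba_error_weeks"],
        kappa_qs=headline["kappa_qs"],
        pma_in_iqr=headline["pma_in_iqr"],
        per_channel=per_channel,
        rejection_fractions={
            t: result.qc_summary[t] for t in result.qc_summary if t in ("fba", "sleep")
        },
    )


def _single_channel_result(bundle, result: AnalysisResult, channel: int):
    """Re-aggregate the stored per-channel outputs using one derivation."""
    from neoeeg import quality_control as qc_mod

    n_seg = result.n_segments
    aggregated = []
    flags = {t: [] for t in ("fba", "sleep")}
    for s in range(n_seg):
        out = result.channel_outputs[s][channel]
        agg = aggregate([out])
        aggregated.append(agg)
        art_frac = qc_mod.artifact_fraction(out.artifact_mask[None, :])
        for task in ("fba", "sleep"):
            thr = qc_mod.QCThresholds(
                attention_min=bundle.attention_thresholds[task],
                qs_uncertainty_halfwidth=bundle.qc_thresholds.qs_uncertainty_halfwidth,
            )
            ch_novel = np.asarray([result.flags[task][s].channel_novelty[channel]])
            flags[task].append(
                qc_mod.combine_flags(
                    qc_mod.flag_artifact(art_frac, thr),
                    qc_mod.majority_novelty(ch_novel),
                    qc_mod.flag_uncertain(
                        agg.max_attention_raw,
                        float(agg.sleep_probs[0]) if task == "sleep" else None,
                        thr,
                        task,
                    ),
                    ch_novel,
                )
            )
    fba_vals = np.asarray([a.fba_weeks for a in aggregated])
    try:
        fba_result = postprocess.global_fba(fba_vals, flags["fba"])
    except InsufficientDataError:
        fba_result = None
    probs = np.asarray([a.sleep_probs for a in aggregated])
    hyp = postprocess.build_hypnogram(
        probs, flags["sleep"], result.segment_rms, bundle.hypnogram_config
    )
    return AnalysisResult(
        n_segments=n_seg,
        start_times=result.start_times,
        channel_labels=[result.channel_labels[channel]],
        channel_outputs=[[result.channel_outputs[s][channel]] for s in range(n_seg)],
        aggregated=aggregated,
        flags=flags,
        fba=fba_result,
        hypnogram=hyp,
        trajectory=None,
        qc_summary={"n_segments": n_seg},
        segment_rms=result.segment_rms,
    )
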