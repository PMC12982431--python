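"""Robust clinical outputs: global FBA with IQR, continuous hypnogram.

The global functional brain age is the median of the per-segment estimates
that passed quality control, with the interquartile range of the retained
estimates as a confidence measure (wider IQR = lower certainty). The
hypnogram is a 2-state (QS vs non-QS) sequence built from smoothed QS
probabilities, with heuristic postprocessing: short unreliable runs are
interpolated from agreeing flanking stages, and artifact-flagged segments
are retained as non-QS when a high-amplitude artifact occurs inside a
predicted wake context (movement during wake is expected, not a reason to
discard the stage call).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from neoeeg.errors import InsufficientDataError

logger = logging.getLogger(__name__)

SEGMENT_MINUTES = 0.5


def _reject_array(flags) -> np.ndarray:
    return np.asarray([bool(f.reject) for f in flags])


@dataclass
class FBAResult:
    """Global FBA estimate (median of retained per-segment estimates)."""

    fba_weeks: float
    iqr_weeks: tuple  # (q1, q3), type-7 quantiles of retained estimates
    n_retained: int
    n_total: int

    @property
    def retained_minutes(self) -> float:
        return self.n_retained * SEGMENT_MINUTES


@dataclass
class HypnogramConfig:
    """Heuristic-postprocessing parameters.

    ``smoothing_window`` (odd, segments) for the reliable-only moving
    average; ``max_gap`` (segments) for interpolation; ``wake_rms_factor``:
    an artifact segment is "high-amplitude" when its pooled RMS exceeds
    this multiple of the recording's median segment RMS.
    """

    smoothing_window: int = 5
    max_gap: int = 4
    wake_rms_factor: float = 3.0


@dataclass
class Hypnogram:
    """Continuous 2-state stage sequence with provenance per segment.

    ``stages[i]`` is ``"QS"``, ``"non-QS"`` or None (unreliable, no stage
    claim); ``provenance[i]`` is one of ``model``, ``interpolated``,
    ``wake-retained``, ``unreliable``. The 3-state probabilities and the
    smoothed QS probability are retained for inspection.
    """

    stages: list
    provenance: list
    p_qs: np.ndarray  # smoothed
    probs_3state: np.ndarray  # (n, 3) aggregated (QS, AS, wake)
    reliable: np.ndarray

    @property
    def n_segments(self) -> int:
        return len(self.stages)


def global_fba(fba_per_segment, flags) -> FBAResult:
    """Median + IQR over quality-control-retained per-segment estimates."""
    vals = np.asarray(fba_per_segment, dtype=float)
    reject = _reject_array(flags)
    retained = vals[~reject]
    if retained.size == 0:
        raise InsufficientDataError("no segments passed quality control")
    q1, q3 = np.percentile(retained, [25.0, 75.0])
    return FBAResult(
        fba_weeks=float(np.median(retained)),
        iqr_weeks=(float(q1), float(q3)),
        n_retained=int(retained.size),
        n_total=int(vals.size),
    )


def smooth_probabilities(qs_probs, flags, window: int = 5) -> np.ndarray:
    """Centered moving average over reliable segments only.

    Flagged segments are dropped from the kernel and the kernel
    renormalized; edges use the truncated window. Positions with no
    reliable neighbour in the window keep their raw value (they carry no
    stage claim downstream anyway).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    p = np.asarray(qs_probs, dtype=float)
    reliable = ~_reject_array(flags)
    half = window // 2
    out = p.copy()
    for i in range(len(p)):
        lo, hi = max(0, i - half), min(len(p), i + half + 1)
        sel = reliable[lo:hi]
        if sel.any():
            out[i] = p[lo:hi][sel].mean()
    return out


def _nearest_reliable(reliable: np.ndarray, i: int, direction: int):
    j = i + direction
    while 0 <= j < len(reliable):
        if reliable[j]:
            return j
        j += direction
    return None


def build_hypnogram(
    sleep_probs: np.ndarray,
    flags,
    segment_rms: np.ndarray | None = None,
    cfg: HypnogramConfig | None = None,
) -> Hypnogram:
    """Assemble the 2-state hypnogram with heuristic postprocessing.

    ``sleep_probs`` is (n, 3) aggregated (QS, AS, wake) probabilities;
    ``segment_rms`` the pooled per-segment RMS of the input signal (used
    by the wake-retention heuristic; when None that heuristic is skipped).

    Order of operations: smooth QS probabilities over reliable segments;
    stage reliable segments by thresholding at 0.5; retain high-amplitude
    artifact segments inside wake context as non-QS; interpolate flagged
    runs of <= ``max_gap`` segments whose flanking stages agree; leave the
    rest unreliable.
    """
    cfg = cfg or HypnogramConfig()
    probs = np.atleast_2d(np.asarray(sleep_probs, dtype=float))
    n = probs.shape[0]
    reject = _reject_array(flags)
    reliable = ~reject
    if n and not reliable.any():
        logger.warning("all segments unreliable; empty hypnogram")
    p_qs = smooth_probabilities(probs[:, 0], flags, cfg.smoothing_window) if n else np.zeros(0)

    stages: list = [None] * n
    provenance = ["unreliable"] * n
    for i in np.flatnonzero(reliable):
        stages[i] = "QS" if p_qs[i] > 0.5 else "non-QS"
        provenance[i] = "model"

    # wake-retention heuristic: high-amplitude artifact inside wake context
    if segment_rms is not None and n:
        rms = np.asarray(segment_rms, dtype=float)
        med = np.median(rms)
        wake_prob = probs[:, 2]
        for i in np.flatnonzero(reject):
            if not flags[i].artifact:
                continue
            if med <= 0 or rms[i] <= cfg.wake_rms_factor * med:
                continue
            ctx = []
            for d in (-1, +1):
                j = _nearest_reliable(reliable, i, d)
                if j is not None:
                    ctx.append(wake_prob[j])
            if ctx and float(np.mean(ctx)) > 0.5:
                stages[i] = "non-QS"
                provenance[i] = "wake-retained"

    # interpolation of short unreliable runs between agreeing flanks
    settled = np.array([s is not None for s in stages])
    i = 0
    while i < n:
        if settled[i]:
            i += 1
            continue
        j = i
        while j < n and not settled[j]:
            j += 1
        run_len = j - i
        if 0 < i and j < n and run_len <= cfg.max_gap:
            left, right = stages[i - 1], stages[j]
            if left == right and left is not None:
                for k in range(i, j):
                    stages[k] = left
                    provenance[k] = "interpolated"
        i = j

    return Hypnogram(
        stages=stages,
        provenance=provenance,
        p_qs=p_qs,
        probs_3state=probs,
        reliable=reliable,
    )


def fba_trajectory(
    fba_per_segment,
    flags,
    window_minutes: float = 60.0,
    min_retained: int = 10,
):
    """Rolling median of retained per-segment FBAs (brain age over time).

    Returns ``(times_s, values)`` with one entry per segment (window
    centered on the segment); windows with fewer than ``min_retained``
    retained segments emit NaN.
    """
    if window_minutes < 10:
        raise ValueError("trajectory window must be >= 10 minutes")
    vals = np.asarray(fba_per_segment, dtype=float)
    reject = _reject_array(flags)
    n = len(vals)
    half = int(round(window_minutes / SEGMENT_MINUTES)) // 2
    times = np.arange(n) * 30.0 + 15.0
    out = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        sel = ~reject[lo:hi]
        if sel.sum() >= min_retained:
            out[i] = np.median(vals[lo:hi][sel])
    return times, out
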