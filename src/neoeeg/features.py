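"""Per-channel-segment feature extraction.

Two feature sets are computed from 30-s channel segments sampled at 64 Hz:

* the nine spectral features used by the novelty-detection models
  (:func:`spectral_features`): relative power in the delta, theta, alpha and
  beta bands, the 75/90/95 % spectral edge frequencies, normalized spectral
  entropy and log total power, all from a Welch periodogram restricted to
  0.5-30 Hz;
* a wider embedding (:func:`embed_segments`) that augments those nine with
  amplitude, spectral-slope and envelope-modulation descriptors and feeds
  the prediction heads.
"""

from __future__ import annotations

import numpy as np
from scipy import signal, stats

#: frequency bands tiling 0.5-30 Hz, in Hz
BANDS = {
    "delta": (0.5, 3.0),
    "theta": (3.0, 8.0),
    "alpha": (8.0, 15.0),
    "beta": (15.0, 30.0),
}

SPECTRAL_FEATURE_NAMES = (
    "relpow_delta",
    "relpow_theta",
    "relpow_alpha",
    "relpow_beta",
    "sef75",
    "sef90",
    "sef95",
    "spectral_entropy",
    "log_total_power",
)

#: sentinel values for zero-power (flat) input
_SENTINEL = np.array([0.0, 0.0, 0.0, 0.0, 0.5, 0.5, 0.5, 0.0, -12.0])

EMBEDDING_FEATURE_NAMES = SPECTRAL_FEATURE_NAMES + (
    "log_sd",
    "spectral_slope",
    "log_env_p90_p10",
    "log_env_min_ratio",
    "relpow_10_30",
    "line_length",
    "kurtosis",
    "zero_cross_rate",
)


def _welch(x: np.ndarray, fs: float, window_s: float = 4.0):
    nperseg = int(round(window_s * fs))
    freqs, psd = signal.welch(
        x, fs=fs, nperseg=min(nperseg, x.shape[-1]), noverlap=None, axis=-1
    )
    return freqs, psd


def spectral_features_batch(x: np.ndarray, fs: float = 64.0):
    """Nine spectral features for a batch of segments.

    Parameters
    ----------
    x : ndarray, shape (m, n_samples)
    fs : sampling rate in Hz

    Returns
    -------
    features : ndarray, shape (m, 9)
    degenerate : ndarray of bool, shape (m,)
        True where the segment carries no power in 0.5-30 Hz; such rows hold
        sentinel values (zero band powers and entropy, SEFs at 0.5 Hz,
        floored log power).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    freqs, psd = _welch(x, fs)
    band_mask = (freqs >= 0.5) & (freqs <= 30.0)
    f = freqs[band_mask]
    p = psd[:, band_mask]
    total = p.sum(axis=-1)
    degenerate = total <= 0.0

    out = np.tile(_SENTINEL, (x.shape[0], 1))
    ok = ~degenerate
    if np.any(ok):
        pok = p[ok]
        tot = total[ok]
        rel = np.empty((pok.shape[0], 4))
        bands = list(BANDS.values())
        for j, (lo, hi) in enumerate(bands):
            # half-open bins so the bands tile 0.5-30 Hz without overlap
            m = (f >= lo) & (f < hi) if j < len(bands) - 1 else (f >= lo) & (f <= hi)
            rel[:, j] = pok[:, m].sum(axis=-1) / tot
        cum = np.cumsum(pok, axis=-1) / tot[:, None]
        sefs = np.empty((pok.shape[0], 3))
        for j, q in enumerate((0.75, 0.90, 0.95)):
            idx = np.argmax(cum >= q, axis=-1)
            sefs[:, j] = f[idx]
        pn = pok / tot[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.nansum(np.where(pn > 0, pn * np.log(pn), 0.0), axis=-1)
        ent /= np.log(pok.shape[-1])
        out[ok, 0:4] = rel
        out[ok, 4:7] = sefs
        out[ok, 7] = ent
        out[ok, 8] = np.log10(tot)
    return out, degenerate


def spectral_features(x: np.ndarray, fs: float = 64.0):
    """Nine spectral features for one channel segment.

    Returns ``(features, degenerate)`` where ``features`` has length 9 in
    the order of :data:`SPECTRAL_FEATURE_NAMES`.
    """
    feats, degen = spectral_features_batch(np.asarray(x)[None, :], fs)
    return feats[0], bool(degen[0])


def _spectral_slope(x: np.ndarray, fs: float) -> np.ndarray:
    """OLS slope of log10 PSD vs log10 frequency on 0.5-16 Hz, per row."""
    freqs, psd = _welch(x, fs)
    m = (freqs >= 0.5) & (freqs <= 16.0)
    lf = np.log10(freqs[m])
    lp = np.log10(np.maximum(psd[:, m], 1e-30))
    lf_c = lf - lf.mean()
    denom = (lf_c**2).sum()
    return (lp * lf_c).sum(axis=-1) / denom


def embed_segments(x: np.ndarray, fs: float = 64.0) -> np.ndarray:
    """Feature embedding for a batch of channel segments.

    ``x`` has shape (m, n_samples); the result has shape
    ``(m, len(EMBEDDING_FEATURE_NAMES))``. The embedding is a fixed,
    channel-agnostic transform: it carries no information about which
    derivation a segment came from.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    m, n = x.shape
    spec, _ = spectral_features_batch(x, fs)

    sd = x.std(axis=-1)
    log_sd = np.log10(np.maximum(sd, 1e-12))
    slope = _spectral_slope(x, fs)

    # envelope modulation from per-3-s-window SDs (discontinuity / trace
    # alternant shows up as a large p90/p10 ratio and a deep minimum)
    win = int(round(3 * fs))
    nwin = n // win
    wsd = x[:, : nwin * win].reshape(m, nwin, win).std(axis=-1)
    wsd = np.maximum(wsd, 1e-12)
    p90 = np.percentile(wsd, 90, axis=-1)
    p10 = np.percentile(wsd, 10, axis=-1)
    env_ratio = np.log10(p90 / p10)
    env_min = np.log10(wsd.min(axis=-1) / np.maximum(sd, 1e-12))

    freqs, psd = _welch(x, fs)
    bm = (freqs >= 0.5) & (freqs <= 30.0)
    hm = (freqs >= 10.0) & (freqs <= 30.0)
    tot = psd[:, bm].sum(axis=-1)
    rel_hi = np.where(tot > 0, psd[:, hm].sum(axis=-1) / np.maximum(tot, 1e-30), 0.0)

    line_length = np.abs(np.diff(x, axis=-1)).mean(axis=-1)
    kurt = stats.kurtosis(x, axis=-1, bias=True)
    zcr = (np.diff(np.signbit(x), axis=-1) != 0).mean(axis=-1)

    return np.column_stack(
        [spec, log_sd, slope, env_ratio, env_min, rel_hi, line_length, kurt, zcr]
    )


#: per-1-s-window features feeding the per-sample artifact head
ARTIFACT_WINDOW_FEATURE_NAMES = ("log_rms", "log_max_abs", "diff_ratio")


def artifact_window_features(x: np.ndarray, fs: float = 64.0, window_s: float = 1.0):
    """Short-window amplitude features for the per-sample artifact head.

    Returns an array of shape (m, n_windows, 3) for input (m, n_samples):
    log RMS, log peak amplitude and the mean absolute first difference
    relative to the RMS (a crude spectral colour proxy distinguishing slow
    high-amplitude movement transients from background).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    m, n = x.shape
    win = int(round(window_s * fs))
    nwin = n // win
    xw = x[:, : nwin * win].reshape(m, nwin, win)
    rms = np.sqrt((xw**2).mean(axis=-1))
    rms = np.maximum(rms, 1e-12)
    mx = np.maximum(np.abs(xw).max(axis=-1), 1e-12)
    dr = np.abs(np.diff(xw, axis=-1)).mean(axis=-1) / rms
    return np.stack([np.log10(rms), np.log10(mx), dr], axis=-1)
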