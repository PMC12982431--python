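"""Recording ingestion and the fixed pre-processing chain.

A recording passes through five stages before prediction:

1. :func:`read_edf` — EDF/EDF+ ingestion (microvolts, vendor prefixes and
   a uniform reference suffix stripped from labels);
2. :func:`derive_bipolar` — re-referencing to the common bipolar montage
   C3-C4, C3-Cz, C3-T4, C4-Cz, C4-T3, which cancels the recording
   reference and makes recordings from different acquisition systems
   comparable;
3. :func:`preprocess` — 0.25-30 Hz zero-phase band-pass and polyphase
   downsampling to 64 Hz;
4. :func:`segment` — non-overlapping 30-s epochs (1920 samples each,
   trailing remainder discarded);
5. :func:`normalize` — per channel, division by the median across
   segments of the per-segment standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal as sps

from neoeeg.errors import FormatError, MontageError, PreprocessError

logger = logging.getLogger(__name__)

SEGMENT_SECONDS = 30
TARGET_FS = 64.0
SEGMENT_SAMPLES = int(SEGMENT_SECONDS * TARGET_FS)

#: alternative 10-20 names accepted for the temporal electrodes
LABEL_ALIASES = {"T7": "T3", "T8": "T4"}

#: the five electrode pairs shared by common neonatal montages
DEFAULT_PAIRS = (
    ("C3", "C4"),
    ("C3", "Cz"),
    ("C3", "T4"),
    ("C4", "Cz"),
    ("C4", "T3"),
)


def canonical_label(label: str) -> str:
    """Case-normalized 10-20 electrode name with T7/T8 mapped to T3/T4."""
    lab = label.strip()
    up = lab.upper()
    if up in LABEL_ALIASES:
        return LABEL_ALIASES[up]
    # normal case convention: letters upper, trailing z lower (Cz, Fz)
    if up.endswith("Z"):
        return up[:-1] + "z"
    return up


@dataclass
class RawRecording:
    """Multi-channel EEG signal matrix in microvolts.

    ``reference_label`` is the electrode all channels are recorded against,
    ``"bipolar"`` after derivation, or ``None`` when unknown.
    """

    signals: np.ndarray  # (n_channels, n_samples), microvolts
    fs: float
    channel_labels: list[str]
    reference_label: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.fs <= 0:
            raise FormatError("sampling rate must be positive")
        if len(self.channel_labels) != self.signals.shape[0]:
            raise FormatError("label count does not match signal rows")
        canon = [canonical_label(c) for c in self.channel_labels]
        if len(set(canon)) != len(canon):
            raise FormatError("channel labels not unique after case normalization")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class DerivationSet:
    """Ordered (anode, cathode) electrode pairs for the bipolar montage."""

    pairs: tuple = DEFAULT_PAIRS

    def __post_init__(self):
        for a, b in self.pairs:
            if canonical_label(a) == canonical_label(b):
                raise MontageError([f"{a}-{b} (anode == cathode)"])

    @property
    def labels(self) -> list[str]:
        return [f"{a}-{b}" for a, b in self.pairs]


@dataclass
class SegmentArray:
    """A recording cut into non-overlapping 30-s epochs at 64 Hz."""

    data: np.ndarray  # (n_channels, n_segments, 1920)
    channel_labels: list[str]
    start_times: np.ndarray  # seconds from recording start
    fs: float = TARGET_FS
    segment_seconds: int = SEGMENT_SECONDS
    normalization_scale: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_segments(self) -> int:
        return self.data.shape[1]


def read_edf(path) -> RawRecording:
    """Read an EDF/EDF+ file into a :class:`RawRecording` (microvolts).

    Vendor prefixes such as ``"EEG "`` are stripped; when every label ends
    in the same ``-<electrode>`` suffix (e.g. ``C3-Cz`` ... ``O2-Cz``) the
    suffix is removed and recorded as the common reference. Annotation
    channels are excluded. Signals declared in mV or V are converted to
    microvolts. Mixed per-signal sampling rates are resampled to the
    maximum by the reader, with a warning.
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises various types on malformed files
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc

    picks = [
        i
        for i, ch in enumerate(raw.ch_names)
        if "annotation" not in ch.lower() and "status" not in ch.lower()
    ]
    if not picks:
        raise FormatError(f"no EEG signals in {path}")
    data = raw.get_data(picks=picks) * 1e6  # MNE returns SI volts
    labels = [raw.ch_names[i] for i in picks]

    cleaned = []
    for lab in labels:
        lab = lab.strip()
        for prefix in ("EEG ", "EEG-", "eeg "):
            if lab.startswith(prefix):
                lab = lab[len(prefix) :]
        cleaned.append(lab.strip())

    reference = None
    if all("-" in lab for lab in cleaned):
        suffixes = {lab.rsplit("-", 1)[1] for lab in cleaned}
        if len(suffixes) == 1:
            reference = suffixes.pop()
            cleaned = [lab.rsplit("-", 1)[0] for lab in cleaned]
        else:
            reference = "bipolar"

    return RawRecording(
        signals=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=cleaned,
        reference_label=reference,
        meta={"recording_id": str(path)},
    )


def derive_bipolar(
    raw: RawRecording, pairs: DerivationSet | Sequence = DerivationSet()
) -> RawRecording:
    """Re-reference a referential recording to the bipolar montage.

    Each derivation is ``anode - cathode`` computed in the referential
    domain, so the common recording reference cancels:
    ``(A - ref) - (B - ref) = A - B``. An electrode equal to the recording
    reference contributes the zero signal. Missing electrodes raise
    :class:`MontageError`; no interpolation is performed.
    """
    if not isinstance(pairs, DerivationSet):
        pairs = DerivationSet(tuple(tuple(p) for p in pairs))
    index = {canonical_label(lab): i for i, lab in enumerate(raw.channel_labels)}
    ref = canonical_label(raw.reference_label) if raw.reference_label else None

    missing = []
    rows = []
    for a, b in pairs.pairs:
        ca, cb = canonical_label(a), canonical_label(b)

        def _get(c, name):
            if c in index:
                return raw.signals[index[c]]
            if ref is not None and c == ref:
                return np.zeros(raw.n_samples)
            missing.append(name)
            return None

        sa = _get(ca, a)
        sb = _get(cb, b)
        if sa is not None and sb is not None:
            rows.append(sa - sb)
    if missing:
        raise MontageError(sorted(set(missing)))

    return RawRecording(
        signals=np.asarray(rows),
        fs=raw.fs,
        channel_labels=pairs.labels,
        reference_label="bipolar",
        meta=dict(raw.meta),
    )


def preprocess(
    raw: RawRecording,
    low_hz: float = 0.25,
    high_hz: float = 30.0,
    fs_out: float = TARGET_FS,
) -> RawRecording:
    """Zero-phase 0.25-30 Hz band-pass, then polyphase resampling to 64 Hz.

    The band-pass is a 4th-order Butterworth applied forward-backward
    (no group delay, so per-sample artifact masks stay aligned with the
    waveform); resampling uses :func:`scipy.signal.resample_poly`, whose
    built-in FIR provides the anti-aliasing.
    """
    if raw.fs < 128:
        raise PreprocessError(
            f"sampling rate {raw.fs} Hz too low; need >= 128 Hz to band-limit at 30 Hz"
        )
    if raw.fs < 2 * high_hz:
        raise PreprocessError("sampling rate below Nyquist for the requested band")

    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=raw.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, raw.signals, axis=-1)

    frac = Fraction(fs_out / raw.fs).limit_denominator(1000)
    out = sps.resample_poly(filtered, frac.numerator, frac.denominator, axis=-1)

    return RawRecording(
        signals=out,
        fs=float(fs_out),
        channel_labels=list(raw.channel_labels),
        reference_label=raw.reference_label,
        meta=dict(raw.meta),
    )


def segment(raw: RawRecording) -> SegmentArray:
    """Cut a 64-Hz recording into non-overlapping 30-s epochs.

    The trailing remainder (< 30 s) is discarded so every segment holds
    exactly 1920 samples. A recording shorter than 30 s yields an empty
    array with a warning.
    """
    if abs(raw.fs - TARGET_FS) > 1e-6:
        raise PreprocessError(f"segment() requires fs == {TARGET_FS}, got {raw.fs}")
    n_seg = raw.n_samples // SEGMENT_SAMPLES
    if n_seg == 0:
        logger.warning(
            "recording shorter than %d s; no segments produced", SEGMENT_SECONDS
        )
    data = raw.signals[:, : n_seg * SEGMENT_SAMPLES].reshape(
        raw.n_channels, n_seg, SEGMENT_SAMPLES
    )
    start_times = np.arange(n_seg) * float(SEGMENT_SECONDS)
    return SegmentArray(
        data=data.copy(),
        channel_labels=list(raw.channel_labels),
        start_times=start_times,
        meta=dict(raw.meta),
    )


def normalize(segs: SegmentArray) -> SegmentArray:
    """Divide each channel by its median per-segment standard deviation.

    The median over segments is robust to occasional high-amplitude
    artifact segments, so background amplitude is mapped to unit scale
    without being dragged by outliers. Channels whose median per-segment
    SD is zero (flat) are left unchanged, recorded under
    ``meta["flat_channels"]`` and logged.
    """
    if segs.n_segments < 1:
        raise PreprocessError("cannot normalize an empty SegmentArray")
    sds = segs.data.std(axis=-1)  # (n_channels, n_segments)
    divisors = np.median(sds, axis=-1)
    flat = divisors == 0.0
    if np.any(flat):
        logger.warning(
            "flat channels (median per-segment SD == 0): %s",
            [segs.channel_labels[i] for i in np.flatnonzero(flat)],
        )
    divisors = np.where(flat, 1.0, divisors)
    meta = dict(segs.meta)
    meta["flat_channels"] = [segs.channel_labels[i] for i in np.flatnonzero(flat)]
    return replace(
        segs,
        data=segs.data / divisors[:, None, None],
        normalization_scale=divisors,
        meta=meta,
    )
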