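"""Minimal 16-bit EDF writer for fixture recordings.

Only writing is implemented here (reading goes through MNE in
:mod:`neoeeg.eeg_io`). The writer produces plain EDF: one data-record
per second, identical sampling rate for all signals, physical dimension
microvolts by default. Values are quantized to the 16-bit digital range
[-32768, 32767] against a per-signal symmetric physical range, so the
round-trip error is bounded by ``physical_range / 2**16``.
"""

from __future__ import annotations

import numpy as np

from neoeeg.errors import FormatError

_DIGITAL_MIN = -32768
_DIGITAL_MAX = 32767


def _field(text: str, width: int) -> bytes:
    b = str(text).encode("ascii")
    if len(b) > width:
        b = b[:width]
    return b.ljust(width)


def write_edf(
    path,
    signals: np.ndarray,
    fs: float,
    channel_labels,
    physical_dim: str = "uV",
    patient_id: str = "X X X X",
    recording_id: str = "Startdate 01-JAN-2000 X X X",
) -> None:
    """Write ``signals`` (channels x samples, in ``physical_dim``) to EDF.

    ``fs`` must be a positive integer (one data-record per second). The
    recording is truncated to a whole number of seconds.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_ch, n_samp = signals.shape
    if len(channel_labels) != n_ch:
        raise FormatError("label count does not match signal rows")
    fs_i = int(round(fs))
    if fs_i <= 0 or abs(fs - fs_i) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    n_rec = n_samp // fs_i
    if n_rec == 0:
        raise FormatError("recording shorter than one EDF data record (1 s)")
    signals = signals[:, : n_rec * fs_i]

    # symmetric physical range per channel; at least +-1 unit to avoid a
    # zero physical span on flat channels
    phys_max = np.maximum(np.abs(signals).max(axis=1), 1.0)
    phys_max = np.ceil(phys_max)

    header = bytearray()
    header += _field("0", 8)
    header += _field(patient_id, 80)
    header += _field(recording_id, 80)
    header += _field("01.01.00", 8)
    header += _field("00.00.00", 8)
    header += _field(str(256 * (1 + n_ch)), 8)
    header += _field("", 44)
    header += _field(str(n_rec), 8)
    header += _field("1", 8)  # record duration, seconds
    header += _field(str(n_ch), 4)

    def sig_fields(values, width):
        out = bytearray()
        for v in values:
            out += _field(v, width)
        return out

    header += sig_fields(channel_labels, 16)
    header += sig_fields(["" for _ in range(n_ch)], 80)  # transducer
    header += sig_fields([physical_dim] * n_ch, 8)
    header += sig_fields([f"{-m:g}" for m in phys_max], 8)
    header += sig_fields([f"{m:g}" for m in phys_max], 8)
    header += sig_fields([str(_DIGITAL_MIN)] * n_ch, 8)
    header += sig_fields([str(_DIGITAL_MAX)] * n_ch, 8)
    header += sig_fields(["" for _ in range(n_ch)], 80)  # prefiltering
    header += sig_fields([str(fs_i)] * n_ch, 8)
    header += sig_fields(["" for _ in range(n_ch)], 32)  # reserved

    gain = (_DIGITAL_MAX - _DIGITAL_MIN) / (2.0 * phys_max)
    digital = np.clip(
        np.rint(signals * gain[:, None]), _DIGITAL_MIN, _DIGITAL_MAX
    ).astype("<i2")

    # records: per second, per signal, fs samples
    recs = digital[:, : n_rec * fs_i].reshape(n_ch, n_rec, fs_i)
    body = recs.transpose(1, 0, 2).tobytes()

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(body)
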