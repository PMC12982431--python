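"""Synthetic neonatal-EEG generator with known ground truth.

The generator emulates the statistical features of neonatal EEG that the
analysis pipeline depends on, not its full physiology:

* a 1/f^beta background whose slope flattens with postmenstrual age
  (beta = 2.4 - 0.05 * (pma - 27)), making functional brain age
  recoverable from the spectrum;
* sleep-stage structure from an alternating-renewal process (AS/QS bouts
  with lognormal durations, exponential wake interruptions), with
  quiet-sleep discontinuity (burst / inter-burst alternation whose
  inter-burst interval shrinks with maturation, approaching a
  trace-alternant-like 50 % duty cycle at term), continuous lower-voltage
  active sleep, and higher-voltage wake with excess 10-30 Hz power;
* injected high-amplitude artifacts (movement, electrode pop,
  flat/disconnection) with an exact per-sample ground-truth mask;
* injected out-of-distribution "novelty" channel-epochs (narrowband tone,
  white noise, ECG-like spike train) with a per-channel-epoch mask.

All randomness flows from one seed; generation is fully deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from neoeeg import edf
from neoeeg.eeg_io import RawRecording, canonical_label

STAGES = ("QS", "AS", "wake")
EPOCH_SECONDS = 30.0

DEFAULT_CHANNELS = ("Fp1", "Fp2", "C3", "C4", "T3", "T4", "O1", "O2")


@dataclass
class GenerationConfig:
    """Study conditions for one synthetic recording.

    ``artifact_rate`` is the expected fraction of 30-s epochs containing an
    injected artifact event; ``novelty_rate`` the expected fraction of
    channel-epochs replaced by out-of-distribution signal.
    """

    pma_weeks: float = 37.0
    duration_min: float = 60.0
    fs: float = 256.0
    channel_labels: tuple = DEFAULT_CHANNELS
    reference_label: str = "Cz"
    artifact_rate: float = 0.2
    novelty_rate: float = 0.02
    seed: int = 0

    # sleep-architecture parameters (minutes)
    as_bout_median_min: float = 20.0
    qs_bout_median_min: float = 15.0
    bout_sigma_log: float = 0.4
    wake_interarrival_median_min: float = 90.0
    wake_bout_median_min: float = 5.0

    # signal-level parameters
    target_sd_uv: float = 15.0  # background SD -> ~60-100 uV peak-to-peak
    interchannel_corr: float = 0.3
    qs_trough_gain: float = 0.25
    as_gain: float = 0.8
    wake_gain: float = 1.1
    wake_beta_excess: float = 0.5  # +50 % relative 10-30 Hz power
    burst_seconds: float = 6.0

    def __post_init__(self):
        if not (27.0 <= self.pma_weeks <= 47.0):
            raise ValueError("pma_weeks must lie in [27, 47]")
        if not (0.0 <= self.artifact_rate <= 1.0 and 0.0 <= self.novelty_rate <= 1.0):
            raise ValueError("artifact_rate and novelty_rate must lie in [0, 1]")

    @property
    def n_epochs(self) -> int:
        return int(self.duration_min * 60.0 // EPOCH_SECONDS)

    def spectral_beta(self) -> float:
        """1/f exponent: steeper (slower EEG) at younger ages."""
        return 2.4 - 0.05 * (self.pma_weeks - 27.0)

    def interburst_seconds(self) -> float:
        """QS inter-burst interval; discontinuity shrinks with maturation."""
        return max(2.0, 14.0 - 0.4 * (self.pma_weeks - 27.0))


@dataclass
class GroundTruth:
    """Reference labels for a generated recording."""

    hypnogram: np.ndarray  # per-epoch stage in {"QS","AS","wake"}
    artifact_mask: np.ndarray  # (n_channels, n_samples) bool at generation fs
    novelty_mask: np.ndarray  # (n_channels, n_epochs) bool
    pma_weeks: float


def _lognormal_minutes(rng, median_min: float, sigma: float) -> float:
    return float(rng.lognormal(mean=math.log(median_min), sigma=sigma))


def sample_hypnogram(cfg: GenerationConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw a per-epoch stage sequence from the alternating-renewal model.

    AS and QS bouts alternate with lognormal durations; wake bouts arrive
    with exponential inter-arrival times and interrupt the cycle. Bouts are
    rounded to whole 30-s epochs with a 2-epoch minimum (truncated only by
    the end of the recording).
    """
    n = cfg.n_epochs
    if n <= 0:
        return np.array([], dtype=object)
    stages = np.empty(n, dtype=object)
    wake_scale = cfg.wake_interarrival_median_min / math.log(2.0)
    cur = STAGES[int(rng.integers(0, 2))]  # start in QS or AS
    next_wake = rng.exponential(wake_scale)
    t = 0  # epoch cursor
    elapsed_min = 0.0
    while t < n:
        if elapsed_min >= next_wake:
            dur = _lognormal_minutes(rng, cfg.wake_bout_median_min, cfg.bout_sigma_log)
            stage = "wake"
            next_wake = elapsed_min + dur + rng.exponential(wake_scale)
        else:
            stage = cur
            med = cfg.qs_bout_median_min if cur == "QS" else cfg.as_bout_median_min
            dur = _lognormal_minutes(rng, med, cfg.bout_sigma_log)
            cur = "AS" if cur == "QS" else "QS"
        n_ep = max(2, int(round(dur * 60.0 / EPOCH_SECONDS)))
        stages[t : t + n_ep] = stage
        t += n_ep
        elapsed_min += n_ep * EPOCH_SECONDS / 60.0
    return stages


def _colored_noise(n: int, beta: float, fs: float, rng: np.random.Generator):
    """Unit-SD noise with PSD ~ 1/f^beta on 0.3-30 Hz, rolled off outside."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    fc = np.clip(f, 0.3, None)
    amp = fc ** (-beta / 2.0)
    hi = f > 30.0
    amp[hi] *= (30.0 / f[hi]) ** 2
    amp[0] = 0.0
    x = np.fft.irfft(spec * amp, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _qs_envelope(n_samples: int, offsets: np.ndarray, cfg: GenerationConfig, fs: float):
    """Burst / inter-burst gain profile for QS samples (by absolute time)."""
    period = cfg.burst_seconds + cfg.interburst_seconds()
    phase = (offsets / fs) % period
    env = np.where(phase < cfg.burst_seconds, 1.0, cfg.qs_trough_gain)
    # smooth the square profile with a ~0.5-s moving average
    k = max(1, int(round(0.5 * fs)))
    kernel = np.ones(k) / k
    return np.convolve(env, kernel, mode="same")


def synthesize_eeg(
    cfg: GenerationConfig, hypnogram: np.ndarray, rng: np.random.Generator
):
    """Generate the referential recording for a stage sequence.

    Returns ``(RawRecording, GroundTruth)`` with empty artifact/novelty
    masks; injection happens in :func:`inject_artifacts` and
    :func:`inject_novelties`.
    """
    n_epochs = len(hypnogram)
    fs = cfg.fs
    samples_per_epoch = int(EPOCH_SECONDS * fs)
    n_samples = n_epochs * samples_per_epoch
    n_ch = len(cfg.channel_labels)
    if n_samples == 0:
        rec = RawRecording(
            signals=np.zeros((n_ch, 0)),
            fs=fs,
            channel_labels=list(cfg.channel_labels),
            reference_label=cfg.reference_label,
            meta={"pma_weeks": cfg.pma_weeks, "recording_id": f"synthetic-{cfg.seed}"},
        )
        truth = GroundTruth(
            hypnogram=np.array([], dtype=object),
            artifact_mask=np.zeros((n_ch, 0), dtype=bool),
            novelty_mask=np.zeros((n_ch, 0), dtype=bool),
            pma_weeks=cfg.pma_weeks,
        )
        return rec, truth

    beta = cfg.spectral_beta()
    shared = _colored_noise(n_samples, beta, fs, rng)
    c = cfg.interchannel_corr
    base = np.empty((n_ch, n_samples))
    for i in range(n_ch):
        indep = _colored_noise(n_samples, beta, fs, rng)
        base[i] = math.sqrt(1.0 - c) * indep + math.sqrt(c) * shared

    # beta-band (10-30 Hz) noise added during wake
    sos = sps.butter(4, [10.0, 30.0], btype="bandpass", fs=fs, output="sos")
    beta_noise = sps.sosfiltfilt(sos, rng.standard_normal((n_ch, n_samples)), axis=-1)
    beta_noise /= np.maximum(beta_noise.std(axis=-1, keepdims=True), 1e-12)
    # fraction of base power in 10-30 Hz (from the shaping spectrum)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    fc = np.clip(f, 0.3, None)
    amp2 = fc**-beta
    amp2[f > 30.0] = 0.0
    amp2[0] = 0.0
    inband = (f >= 0.3) & (f <= 30.0)
    hi = (f >= 10.0) & (f <= 30.0)
    rel_hi = amp2[hi].sum() / amp2[inband].sum()

    gain = np.ones(n_samples)
    add_beta = np.zeros(n_samples)
    for e in range(n_epochs):
        sl = slice(e * samples_per_epoch, (e + 1) * samples_per_epoch)
        stage = hypnogram[e]
        if stage == "QS":
            offs = np.arange(sl.start, sl.stop)
            gain[sl] = _qs_envelope(samples_per_epoch, offs, cfg, fs)
        elif stage == "AS":
            gain[sl] = cfg.as_gain
        else:  # wake
            gain[sl] = cfg.wake_gain
            add_beta[sl] = math.sqrt(cfg.wake_beta_excess * rel_hi)

    signals = base * gain + beta_noise * add_beta
    signals *= cfg.target_sd_uv / np.maximum(signals.std(axis=-1, keepdims=True), 1e-12)

    rec = RawRecording(
        signals=signals,
        fs=fs,
        channel_labels=list(cfg.channel_labels),
        reference_label=cfg.reference_label,
        meta={"pma_weeks": cfg.pma_weeks, "recording_id": f"synthetic-{cfg.seed}"},
    )
    truth = GroundTruth(
        hypnogram=np.asarray(hypnogram, dtype=object),
        artifact_mask=np.zeros((n_ch, n_samples), dtype=bool),
        novelty_mask=np.zeros((n_ch, n_epochs), dtype=bool),
        pma_weeks=cfg.pma_weeks,
    )
    return rec, truth


def _movement_event(rng, fs, n_samples, channel_sds, start, dur_samp, channels):
    """Low-frequency (<5 Hz) high-amplitude transient; returns added signal."""
    sos = sps.butter(4, 5.0, btype="lowpass", fs=fs, output="sos")
    out = {}
    taper = np.hanning(dur_samp)
    for ch in channels:
        noise = sps.sosfiltfilt(sos, rng.standard_normal(dur_samp))
        noise /= max(noise.std(), 1e-12)
        amp = rng.uniform(5.0, 15.0) * channel_sds[ch]
        out[ch] = amp * noise * taper
    return out


def inject_artifacts(
    rec: RawRecording,
    truth: GroundTruth,
    cfg: GenerationConfig,
    rng: np.random.Generator,
):
    """Inject movement, electrode-pop and flat-channel artifacts.

    Each 30-s epoch receives an event with probability ``artifact_rate``;
    predicted-wake retention heuristics are exercisable because wake epochs
    additionally receive movement events at twice the base rate. Movement
    transients hit 1 to all channels; electrode pops a single channel;
    flat/disconnection events the whole montage. The artifact mask is set
    exactly on modified samples.
    """
    n_epochs = len(truth.hypnogram)
    if n_epochs == 0 or cfg.artifact_rate == 0.0:
        return rec, truth
    fs = rec.fs
    spe = int(EPOCH_SECONDS * fs)
    n_ch, n_samples = rec.signals.shape
    signals = rec.signals.copy()
    mask = truth.artifact_mask.copy()
    channel_sds = signals.std(axis=-1)

    # epochs are selected first (binomial at artifact_rate, so the affected
    # fraction tracks the configured rate); each contiguous run of selected
    # epochs then hosts one event confined to the run's extent
    wake = np.asarray([s == "wake" for s in truth.hypnogram])
    selected = rng.random(n_epochs) < cfg.artifact_rate
    # wake epochs attract movement artifacts at twice the base rate
    selected |= wake & (rng.random(n_epochs) < cfg.artifact_rate)

    # end of the contiguous selected run each epoch belongs to (sample index)
    run_end = np.empty(n_epochs, dtype=int)
    e = n_epochs - 1
    end = None
    while e >= 0:
        if selected[e]:
            if end is None:
                end = (e + 1) * spe
            run_end[e] = end
        else:
            end = None
        e -= 1

    for e in np.flatnonzero(selected):
        epoch_start = e * spe
        if wake[e]:
            kind = "movement"  # wake's extra events are movement by design
        else:
            kind = rng.choice(["movement", "pop", "flat"], p=[0.5, 0.25, 0.25])
        room = run_end[e] - epoch_start
        if kind == "movement":
            # events sit fully inside the selected run so a 30-s-plus event
            # obscures its whole epoch (high artifact content)
            dur = min(int(rng.uniform(5.0, 60.0) * fs), room, n_samples - epoch_start)
            start = epoch_start + int(rng.integers(0, room - dur + 1))
            k = int(rng.integers(1, n_ch + 1))
            chans = rng.choice(n_ch, size=k, replace=False)
            added = _movement_event(rng, fs, n_samples, channel_sds, start, dur, chans)
            for ch, sig_add in added.items():
                signals[ch, start : start + dur] += sig_add
                mask[ch, start : start + dur] = True
        elif kind == "pop":
            ch = int(rng.integers(0, n_ch))
            tau = rng.uniform(2.0, 10.0)
            dur = min(int(5 * tau * fs), room, n_samples - epoch_start)
            start = epoch_start + int(rng.integers(0, room - dur + 1))
            t = np.arange(dur) / fs
            amp = rng.uniform(5.0, 15.0) * channel_sds[ch] * rng.choice([-1, 1])
            signals[ch, start : start + dur] += amp * np.exp(-t / tau)
            mask[ch, start : start + dur] = True
        else:  # flat / disconnection: the whole montage drops out (a
            # single flat electrode would leave its bipolar derivations
            # carrying the other electrode's normal signal)
            dur = min(int(rng.uniform(10.0, 120.0) * fs), room, n_samples - epoch_start)
            start = epoch_start + int(rng.integers(0, room - dur + 1))
            signals[:, start : start + dur] *= 0.01
            mask[:, start : start + dur] = True

    out = RawRecording(
        signals=signals,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        reference_label=rec.reference_label,
        meta=dict(rec.meta),
    )
    return out, GroundTruth(truth.hypnogram, mask, truth.novelty_mask, truth.pma_weeks)


def inject_novelties(
    rec: RawRecording,
    truth: GroundTruth,
    cfg: GenerationConfig,
    rng: np.random.Generator,
):
    """Replace random channel-epochs with out-of-distribution signal.

    The three archetypes (20-Hz-dominant narrowband tone, spectrally flat
    white noise, 2.2-Hz ECG-like spike train) are all spectrally alien to
    the 1/f background family, so a spectral-feature novelty detector can
    separate them.
    """
    n_epochs = len(truth.hypnogram)
    if n_epochs == 0 or cfg.novelty_rate == 0.0:
        return rec, truth
    fs = rec.fs
    spe = int(EPOCH_SECONDS * fs)
    n_ch = rec.n_channels
    signals = rec.signals.copy()
    novelty = truth.novelty_mask.copy()

    hits = rng.random((n_ch, n_epochs)) < cfg.novelty_rate
    t_epoch = np.arange(spe) / fs
    for ch, e in zip(*np.nonzero(hits)):
        sl = slice(e * spe, (e + 1) * spe)
        sd = max(signals[ch, sl].std(), 1.0)
        kind = rng.choice(["narrowband", "white", "ecg"])
        if kind == "narrowband":
            phase = rng.uniform(0, 2 * np.pi)
            x = np.sin(2 * np.pi * 20.0 * t_epoch + phase)
            x += 0.05 * rng.standard_normal(spe)
        elif kind == "white":
            x = rng.standard_normal(spe)
        else:
            x = np.zeros(spe)
            width = int(0.04 * fs)
            pulse = sps.windows.gaussian(2 * width + 1, std=width / 2.0)
            period = int(fs / 2.2)
            for p0 in range(0, spe - 2 * width - 1, period):
                x[p0 : p0 + 2 * width + 1] += 5.0 * pulse
            x += 0.1 * rng.standard_normal(spe)
        x = x / max(x.std(), 1e-12) * sd
        signals[ch, sl] = x
        novelty[ch, e] = True

    out = RawRecording(
        signals=signals,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        reference_label=rec.reference_label,
        meta=dict(rec.meta),
    )
    return out, GroundTruth(truth.hypnogram, truth.artifact_mask, novelty, truth.pma_weeks)


def generate_recording(cfg: GenerationConfig):
    """Full generation chain: hypnogram -> EEG -> artifacts -> novelties."""
    rng = np.random.default_rng(cfg.seed)
    hyp = sample_hypnogram(cfg, rng)
    rec, truth = synthesize_eeg(cfg, hyp, rng)
    rec, truth = inject_artifacts(rec, truth, cfg, rng)
    rec, truth = inject_novelties(rec, truth, cfg, rng)
    return rec, truth


# ---------------------------------------------------------------------------
# ground-truth remapping helpers (referential masks -> bipolar derivations)
# ---------------------------------------------------------------------------


def derivation_masks(
    truth: GroundTruth,
    channel_labels,
    reference_label: str,
    pairs,
    fs_in: float,
    fs_out: float = 64.0,
):
    """Map referential ground-truth masks onto bipolar derivations at 64 Hz.

    A derivation sample is artifactual when either of its electrodes is
    (the reference is taken as clean); a derivation-epoch is a novelty when
    either electrode-epoch is. ``fs_in / fs_out`` must be an integer
    factor; a 64-Hz sample is flagged when any source sample in its span is.

    Returns ``(artifact_mask_64, novelty_mask)`` with shapes
    (n_derivations, n_samples_64) and (n_derivations, n_epochs).
    """
    factor = fs_in / fs_out
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("fs_in must be an integer multiple of fs_out")
    factor = int(round(factor))
    index = {canonical_label(c): i for i, c in enumerate(channel_labels)}
    ref = canonical_label(reference_label)
    n_samples = truth.artifact_mask.shape[1]
    n64 = n_samples // factor
    n_epochs = truth.novelty_mask.shape[1]

    art = np.zeros((len(pairs), n64), dtype=bool)
    nov = np.zeros((len(pairs), n_epochs), dtype=bool)
    for d, (a, b) in enumerate(pairs):
        rows_a = []
        for lab in (a, b):
            c = canonical_label(lab)
            if c in index:
                rows_a.append(index[c])
            elif c != ref:
                raise KeyError(f"electrode {lab} not in ground truth")
        if rows_a:
            m = np.any(truth.artifact_mask[rows_a], axis=0)
            art[d] = m[: n64 * factor].reshape(n64, factor).any(axis=-1)
            nov[d] = np.any(truth.novelty_mask[rows_a], axis=0)
    return art, nov


def epoch_artifact_fraction(mask_64: np.ndarray, n_epochs: int | None = None):
    """Per-epoch fraction of artifact samples, pooled over derivations."""
    spe = int(EPOCH_SECONDS * 64)
    n_ch, n = mask_64.shape
    if n_epochs is None:
        n_epochs = n // spe
    m = mask_64[:, : n_epochs * spe].reshape(n_ch, n_epochs, spe)
    return m.mean(axis=(0, 2))


# ---------------------------------------------------------------------------
# fixture writing / loading
# ---------------------------------------------------------------------------


def _mask_to_runs(mask: np.ndarray):
    """Run-length encode a (channels x samples) boolean mask."""
    rows = []
    for ch in range(mask.shape[0]):
        m = mask[ch]
        if not m.any():
            continue
        d = np.diff(m.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if m[0]:
            starts = np.r_[0, starts]
        if m[-1]:
            ends = np.r_[ends, len(m)]
        for s, e in zip(starts, ends):
            rows.append((ch, int(s), int(e)))
    return rows


def _runs_to_mask(rows, n_channels: int, n_samples: int):
    mask = np.zeros((n_channels, n_samples), dtype=bool)
    for ch, s, e in rows:
        mask[int(ch), int(s) : int(e)] = True
    return mask


def write_fixture(rec: RawRecording, truth: GroundTruth, directory, cfg=None) -> None:
    """Write a recording + ground truth as plain files.

    ``recording.edf`` (16-bit, microvolts), ``hypnogram.csv``
    (epoch_index, onset_s, stage), ``artifact_mask.csv`` (run-length:
    channel_index, start_sample, end_sample at the generation rate),
    ``novelty_mask.csv`` (channel_index, epoch_index) and ``meta.json``
    (PMA, seed, config echo).
    """
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    # labels carry the reference as a uniform suffix ("C3-Cz"), the usual
    # clinical export convention, so plain EDF ingestion recovers it
    if rec.reference_label and rec.reference_label not in ("bipolar",):
        labels = [f"{ch}-{rec.reference_label}" for ch in rec.channel_labels]
    else:
        labels = list(rec.channel_labels)
    edf.write_edf(directory / "recording.edf", rec.signals, rec.fs, labels)
    n_epochs = len(truth.hypnogram)
    pd.DataFrame(
        {
            "epoch_index": np.arange(n_epochs),
            "onset_s": np.arange(n_epochs) * EPOCH_SECONDS,
            "stage": list(truth.hypnogram),
        }
    ).to_csv(directory / "hypnogram.csv", index=False)

    pd.DataFrame(
        _mask_to_runs(truth.artifact_mask),
        columns=["channel_index", "start_sample", "end_sample"],
    ).to_csv(directory / "artifact_mask.csv", index=False)

    ch, ep = np.nonzero(truth.novelty_mask)
    pd.DataFrame({"channel_index": ch, "epoch_index": ep}).to_csv(
        directory / "novelty_mask.csv", index=False
    )

    meta = {
        "pma_weeks": truth.pma_weeks,
        "fs": rec.fs,
        "n_samples": rec.n_samples,
        "channel_labels": list(rec.channel_labels),
        "reference_label": rec.reference_label,
    }
    if cfg is not None:
        meta["config"] = asdict(cfg)
        meta["seed"] = cfg.seed
    with open(directory / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def load_fixture(directory):
    """Read a fixture directory back into ``(RawRecording, GroundTruth)``."""
    import pandas as pd

    from neoeeg.eeg_io import read_edf

    directory = Path(directory)
    with open(directory / "meta.json") as fh:
        meta = json.load(fh)
    rec = read_edf(directory / "recording.edf")
    rec.reference_label = meta.get("reference_label")
    rec.meta["pma_weeks"] = meta["pma_weeks"]

    hyp = pd.read_csv(directory / "hypnogram.csv")
    hypnogram = np.asarray(hyp["stage"].tolist(), dtype=object)
    runs = pd.read_csv(directory / "artifact_mask.csv")
    mask = _runs_to_mask(
        runs.itertuples(index=False), rec.n_channels, meta["n_samples"]
    )
    nov = pd.read_csv(directory / "novelty_mask.csv")
    novelty = np.zeros((rec.n_channels, len(hypnogram)), dtype=bool)
    novelty[nov["channel_index"].to_numpy(), nov["epoch_index"].to_numpy()] = True
    truth = GroundTruth(hypnogram, mask, novelty, meta["pma_weeks"])
    return rec, truth
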