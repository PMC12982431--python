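"""Channel-agnostic multi-task predictor with attention aggregation.

One shared encoder is applied to every channel of every 30-s segment with
identical parameters — channel identity is never an input — and four heads
produce, per channel: (i) a per-sample artifact probability/mask, (ii)
3-class sleep-stage probabilities (QS, AS, wake), (iii) a functional brain
age estimate in weeks, and (iv) a strictly positive unnormalized attention
weight. Linear normalization of the attention weights over the included
channels yields the convex combination used to aggregate per-channel sleep
and FBA predictions into one global per-segment output; the raw
(unnormalized) maximum over channels is kept for the uncertainty criterion.

The encoder is a fixed spectral/envelope feature embedding
(:func:`neoeeg.features.embed_segments`); the heads are gradient-boosted
trees — FBA regression, sleep classification, attention, and a 1-s-window
classifier for the artifact mask — trained jointly from heterogeneously
labeled recordings: every example contributes only to the heads for which
it carries labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier, HistGradientBoostingRegressor
from sklearn.preprocessing import StandardScaler

from neoeeg import features
from neoeeg.eeg_io import SEGMENT_SAMPLES, SegmentArray
from neoeeg.errors import AggregationError, NeoeegError

logger = logging.getLogger(__name__)

STAGES = ("QS", "AS", "wake")

#: slope of the softplus attention transform; attention_raw =
#: softplus(ATTENTION_SCALE * (score - 0.5)) where score is the attention
#: head's predicted age-accuracy of the channel, so an informative channel
#: maps to ~2-4 and an unusable one to ~0.02
ATTENTION_SCALE = 8.0

ARTIFACT_PROB_THRESHOLD = 0.5


@dataclass
class EncoderConfig:
    """Encoder/head hyperparameters.

    The embedding is deterministic, so the tunables are the head fit
    parameters. ``artifact_window_s`` sets the resolution of the per-sample
    artifact head (window probabilities are upsampled back to 1920 logits).
    """

    fs: float = 64.0
    segment_samples: int = SEGMENT_SAMPLES
    artifact_window_s: float = 1.0
    embedding_dim: int = len(features.EMBEDDING_FEATURE_NAMES)
    max_iter: int = 200
    learning_rate: float = 0.1
    early_stopping: bool = True
    validation_fraction: float = 0.1


@dataclass
class ChannelOutputs:
    """Per-channel, per-segment model outputs."""

    artifact_probs: np.ndarray  # (1920,) in [0,1]
    artifact_mask: np.ndarray  # (1920,) bool, probs > 0.5
    sleep_probs: np.ndarray  # (3,) simplex over (QS, AS, wake)
    fba_weeks: float
    attention_raw: float  # > 0, unnormalized


@dataclass
class AggregatedOutputs:
    """Attention-weighted global per-segment outputs."""

    sleep_probs: np.ndarray
    fba_weeks: float
    max_attention_raw: float
    weights_normalized: np.ndarray  # per input channel; 0 on excluded


def softplus(x):
    return np.logaddexp(0.0, x)


def aggregate(outputs, excluded=None) -> AggregatedOutputs:
    """Aggregate per-channel outputs by linearly normalized attention.

    ``w_i = a_i / sum_j a_j`` over the included channels (excluded channels
    get weight exactly 0), so the aggregated sleep probabilities stay on
    the simplex and the raw attention scale stays interpretable.
    ``max_attention_raw`` is taken over included channels *before*
    normalization. Raises :class:`AggregationError` when every channel is
    excluded.
    """
    n = len(outputs)
    excluded = np.zeros(n, dtype=bool) if excluded is None else np.asarray(excluded)
    included = np.flatnonzero(~excluded)
    if included.size == 0:
        raise AggregationError("all channels excluded from aggregation")
    att = np.array([outputs[i].attention_raw for i in included], dtype=float)
    w = att / att.sum()
    weights = np.zeros(n)
    weights[included] = w
    sleep = np.sum(
        [w_i * outputs[i].sleep_probs for w_i, i in zip(w, included)], axis=0
    )
    fba = float(np.sum([w_i * outputs[i].fba_weeks for w_i, i in zip(w, included)]))
    return AggregatedOutputs(
        sleep_probs=sleep,
        fba_weeks=fba,
        max_attention_raw=float(att.max()),
        weights_normalized=weights,
    )


@dataclass
class TrainingExample:
    """One recording's worth of channel-segment inputs with optional labels.

    ``segments`` is a normalized :class:`SegmentArray`; any label may be
    None — a task's loss only sees examples where its label exists.
    ``artifact_mask`` is per-derivation per-sample at 64 Hz;
    ``exclude_epochs`` marks channel-epochs (derivations x epochs) to keep
    out of the age/sleep fits (e.g. artifact- or novelty-bearing epochs).
    """

    segments: SegmentArray
    age_weeks: float | None = None
    hypnogram: np.ndarray | None = None  # per-epoch stage strings
    artifact_mask: np.ndarray | None = None  # (n_channels, n_samples_64) bool
    exclude_epochs: np.ndarray | None = None  # (n_channels, n_epochs) bool


class NeonatalModel:
    """The trained multi-task model (encoder config + four fitted heads)."""

    def __init__(self, config: EncoderConfig | None = None):
        self.config = config or EncoderConfig()
        self.fba_head = None
        self.sleep_head = None
        self.artifact_head = None
        self.artifact_scaler = None
        self.attention_head = None
        self.history: dict = {}

    # -- encoding -----------------------------------------------------------

    def _check_input(self, x):
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise NeoeegError("non-finite values in model input")
        return x

    def _encode_batch(self, x: np.ndarray):
        """All four heads over a (m, 1920) batch of channel segments."""
        cfg = self.config
        emb = features.embed_segments(x, cfg.fs)

        if self.fba_head is not None:
            fba = self.fba_head.predict(emb)
        else:
            fba = np.full(len(x), np.nan)
        if self.sleep_head is not None:
            raw = self.sleep_head.predict_proba(emb)
            # align predict_proba column order with STAGES; a stage absent
            # from the training labels gets probability zero
            probs = np.zeros((len(emb), len(STAGES)))
            for j, cls in enumerate(self.sleep_head.classes_):
                probs[:, STAGES.index(cls)] = raw[:, j]
        else:
            probs = np.full((len(x), 3), 1.0 / 3.0)

        wf = features.artifact_window_features(x, cfg.fs, cfg.artifact_window_s)
        m, nwin, nf = wf.shape
        if self.artifact_head is not None:
            flat = self.artifact_scaler.transform(wf.reshape(-1, nf))
            pw = self.artifact_head.predict_proba(flat)[:, 1].reshape(m, nwin)
        else:
            pw = np.zeros((m, nwin))
        # nearest-neighbour upsampling of window probabilities to per-sample
        win = int(round(cfg.artifact_window_s * cfg.fs))
        probs_samp = np.repeat(pw, win, axis=-1)
        if probs_samp.shape[-1] < x.shape[-1]:
            pad = x.shape[-1] - probs_samp.shape[-1]
            probs_samp = np.pad(probs_samp, ((0, 0), (0, pad)), mode="edge")
        probs_samp = probs_samp[:, : x.shape[-1]]

        if self.attention_head is not None:
            clean = self.attention_head.predict(emb)
        else:
            clean = np.ones(len(x))
        attention = softplus(ATTENTION_SCALE * (clean - 0.5))
        return fba, probs, probs_samp, attention

    def encode_channel(self, segment_channel: np.ndarray) -> ChannelOutputs:
        """Apply the shared encoder + heads to one 1920-sample channel."""
        x = self._check_input(segment_channel)
        if x.shape != (self.config.segment_samples,):
            raise NeoeegError(
                f"expected a {self.config.segment_samples}-sample vector"
            )
        fba, probs, psamp, att = self._encode_batch(x[None, :])
        return ChannelOutputs(
            artifact_probs=psamp[0],
            artifact_mask=psamp[0] > ARTIFACT_PROB_THRESHOLD,
            sleep_probs=probs[0],
            fba_weeks=float(fba[0]),
            attention_raw=float(att[0]),
        )

    # -- inference ----------------------------------------------------------

    def predict_recording(self, segs: SegmentArray):
        """Per-segment channel outputs plus the unexcluded aggregate.

        Returns ``(channel_outputs, aggregated)`` where ``channel_outputs``
        is a list (over segments) of lists (over channels) of
        :class:`ChannelOutputs` and ``aggregated`` the corresponding
        :class:`AggregatedOutputs` with no channel exclusions (quality
        control applies exclusions and re-aggregates downstream).
        """
        n_ch, n_seg = segs.n_channels, segs.n_segments
        if n_seg == 0:
            return [], []
        x = self._check_input(segs.data.transpose(1, 0, 2).reshape(-1, segs.data.shape[-1]))
        fba, probs, psamp, att = self._encode_batch(x)
        channel_outputs = []
        aggregated = []
        for s in range(n_seg):
            outs = []
            for c in range(n_ch):
                i = s * n_ch + c
                outs.append(
                    ChannelOutputs(
                        artifact_probs=psamp[i],
                        artifact_mask=psamp[i] > ARTIFACT_PROB_THRESHOLD,
                        sleep_probs=probs[i],
                        fba_weeks=float(fba[i]),
                        attention_raw=float(att[i]),
                    )
                )
            channel_outputs.append(outs)
            aggregated.append(aggregate(outs))
        return channel_outputs, aggregated


def _collect_training_arrays(examples, cfg: EncoderConfig):
    """Flatten recordings into per-task design matrices."""
    emb_all, age_y, age_rows = [], [], []
    sleep_y, sleep_rows = [], []
    art_X, art_y = [], []
    att_y, att_rows = [], []
    row0 = 0
    win = int(round(cfg.artifact_window_s * cfg.fs))
    for ex in examples:
        segs = ex.segments
        n_ch, n_seg = segs.n_channels, segs.n_segments
        x = segs.data.transpose(1, 0, 2).reshape(-1, segs.data.shape[-1])
        emb_all.append(features.embed_segments(x, cfg.fs))
        excl = (
            ex.exclude_epochs
            if ex.exclude_epochs is not None
            else np.zeros((n_ch, n_seg), dtype=bool)
        )
        if ex.artifact_mask is not None:
            spe = segs.data.shape[-1]
            m = ex.artifact_mask[:, : n_seg * spe].reshape(n_ch, n_seg, spe)
            wf = features.artifact_window_features(x, cfg.fs, cfg.artifact_window_s)
            nwin = wf.shape[1]
            wm = m[:, :, : nwin * win].reshape(n_ch, n_seg, nwin, win).mean(axis=-1)
            labels = (wm > 0.5).transpose(1, 0, 2).reshape(-1)
            art_X.append(wf.reshape(-1, wf.shape[-1]))
            art_y.append(labels)
        for s in range(n_seg):
            for c in range(n_ch):
                row = row0 + s * n_ch + c
                clean_epoch = not excl[c, s]
                if ex.age_weeks is not None and clean_epoch:
                    age_rows.append(row)
                    age_y.append(ex.age_weeks)
                if ex.hypnogram is not None and clean_epoch:
                    sleep_rows.append(row)
                    sleep_y.append(ex.hypnogram[s])
                if ex.age_weeks is not None:
                    # attention rows: every channel-epoch of age-labeled
                    # recordings, including artifact/novelty epochs (the
                    # target is computed from the FBA head's residual
                    # after that head is fitted, so unusable epochs earn
                    # low attention)
                    att_rows.append(row)
                    att_y.append(ex.age_weeks)
        row0 += n_seg * n_ch
    emb = np.vstack(emb_all) if emb_all else np.empty((0, cfg.embedding_dim))
    return {
        "emb": emb,
        "age": (np.asarray(age_rows, dtype=int), np.asarray(age_y, dtype=float)),
        "sleep": (np.asarray(sleep_rows, dtype=int), np.asarray(sleep_y, dtype=object)),
        "artifact": (
            np.vstack(art_X) if art_X else np.empty((0, 3)),
            np.concatenate(art_y) if art_y else np.empty(0, dtype=bool),
        ),
        "attention": (np.asarray(att_rows, dtype=int), np.asarray(att_y, dtype=float)),
    }


def train(
    model: NeonatalModel,
    examples,
    seed: int = 0,
) -> NeonatalModel:
    """Fit the four heads from heterogeneously labeled recordings.

    ``examples`` is a sequence of :class:`TrainingExample`; each head is
    fitted only on the examples carrying its labels (a task with no labels
    at all is dropped with a warning and its head left unfitted). Boosted
    heads use seeded early stopping on an internal validation split;
    ``model.history`` records per-task sample counts and validation
    metrics.
    """
    cfg = model.config
    arrays = _collect_training_arrays(examples, cfg)
    emb = arrays["emb"]
    history: dict = {}

    age_rows, age_y = arrays["age"]
    if len(age_rows):
        model.fba_head = HistGradientBoostingRegressor(
            loss="absolute_error",
            max_iter=cfg.max_iter,
            learning_rate=cfg.learning_rate,
            early_stopping=cfg.early_stopping,
            validation_fraction=cfg.validation_fraction,
            random_state=seed,
        )
        model.fba_head.fit(emb[age_rows], age_y)
        val = np.abs(model.fba_head.predict(emb[age_rows]) - age_y).mean()
        history["fba"] = {"n": int(len(age_rows)), "train_l1_weeks": float(val)}
    else:
        logger.warning("no age-labeled examples; FBA head not trained")

    sleep_rows, sleep_y = arrays["sleep"]
    if len(sleep_rows):
        model.sleep_head = HistGradientBoostingClassifier(
            max_iter=cfg.max_iter,
            learning_rate=cfg.learning_rate,
            early_stopping=cfg.early_stopping,
            validation_fraction=cfg.validation_fraction,
            random_state=seed + 1,
        )
        model.sleep_head.fit(emb[sleep_rows], sleep_y.astype(str))
        acc = (model.sleep_head.predict(emb[sleep_rows]) == sleep_y.astype(str)).mean()
        history["sleep"] = {"n": int(len(sleep_rows)), "train_accuracy": float(acc)}
    else:
        logger.warning("no sleep-labeled examples; sleep head not trained")

    art_X, art_y = arrays["artifact"]
    if len(art_y) and art_y.any() and not art_y.all():
        # boosted trees: artifact classes are non-monotone in amplitude
        # (movement transients are high-RMS, disconnections near-zero)
        model.artifact_scaler = StandardScaler().fit(art_X)
        model.artifact_head = HistGradientBoostingClassifier(
            max_iter=cfg.max_iter,
            learning_rate=cfg.learning_rate,
            early_stopping=cfg.early_stopping,
            validation_fraction=cfg.validation_fraction,
            random_state=seed + 2,
        )
        model.artifact_head.fit(model.artifact_scaler.transform(art_X), art_y)
        acc = model.artifact_head.score(model.artifact_scaler.transform(art_X), art_y)
        history["artifact"] = {"n": int(len(art_y)), "train_accuracy": float(acc)}
    else:
        logger.warning("no artifact-labeled windows (or single class); head not trained")

    att_rows, att_age = arrays["attention"]
    if len(att_rows) and model.fba_head is not None:
        # attention target: per-channel-epoch age accuracy of the FBA head,
        # mapped through exp(-|residual| / 2 weeks). Channel-epochs whose
        # spectral content misleads the age estimate (artifacts, novelties,
        # idiosyncratic background) earn low attention, and the target is
        # continuous so the calibrated 1st-percentile threshold sits on a
        # distribution with genuine spread.
        resid = np.abs(model.fba_head.predict(emb[att_rows]) - att_age)
        target = np.exp(-resid / 2.0)
        model.attention_head = HistGradientBoostingRegressor(
            max_iter=cfg.max_iter,
            learning_rate=cfg.learning_rate,
            early_stopping=cfg.early_stopping,
            validation_fraction=cfg.validation_fraction,
            random_state=seed + 3,
        )
        model.attention_head.fit(emb[att_rows], target)
        history["attention"] = {"n": int(len(att_rows))}
    else:
        logger.warning("no attention targets; uniform attention will be used")

    model.history = history
    return model
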