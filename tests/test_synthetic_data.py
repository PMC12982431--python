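"""Generator properties: determinism, age/stage structure, injections."""

import json

import numpy as np
import pytest

from neoeeg.eeg_io import derive_bipolar, normalize, preprocess, segment
from neoeeg.features import embed_segments
from neoeeg.synthetic_data import (
    GenerationConfig,
    derivation_masks,
    generate_recording,
    inject_artifacts,
    inject_novelties,
    load_fixture,
    sample_hypnogram,
    synthesize_eeg,
    write_fixture,
)


def _cfg(**kw):
    defaults = dict(pma_weeks=35, duration_min=10, seed=0, artifact_rate=0.0, novelty_rate=0.0)
    defaults.update(kw)
    return GenerationConfig(**defaults)


class TestHypnogram:
    def test_single_epoch_recording(self):
        cfg = _cfg(duration_min=0.5)
        hyp = sample_hypnogram(cfg, np.random.default_rng(0))
        assert len(hyp) == 1
        assert hyp[0] in ("QS", "AS", "wake")

    def test_seeded_determinism(self):
        cfg = _cfg(duration_min=120)
        a = sample_hypnogram(cfg, np.random.default_rng(5))
        b = sample_hypnogram(cfg, np.random.default_rng(5))
        assert list(a) == list(b)

    def test_qs_fraction_in_expected_band(self):
        """Monte-Carlo over the renewal process: QS occupies 25-55 %."""
        fracs = []
        cfg = _cfg(duration_min=600)
        for s in range(200):
            hyp = sample_hypnogram(cfg, np.random.default_rng(s))
            fracs.append(np.mean([x == "QS" for x in hyp]))
        assert 0.25 <= np.mean(fracs) <= 0.55

    def test_minimum_bout_length(self):
        cfg = _cfg(duration_min=300)
        hyp = sample_hypnogram(cfg, np.random.default_rng(3))
        runs = [len(list(g)) for _, g in __import__("itertools").groupby(hyp)]
        # interior bouts are >= 2 epochs (the last may be truncated)
        assert all(r >= 2 for r in runs[:-1])


class TestSynthesizeEeg:
    def test_spectral_slope_steeper_at_younger_age(self):
        slopes = {}
        for pma in (27, 45):
            cfg = _cfg(pma_weeks=pma, duration_min=10, seed=11)
            rec, _ = generate_recording(cfg)
            segs = normalize(segment(preprocess(derive_bipolar(rec))))
            emb = embed_segments(segs.data.reshape(-1, 1920))
            slopes[pma] = emb[:, 10].mean()
        assert slopes[27] < slopes[45]

    def test_age_monotonic_slope_on_grid(self):
        """Mean fitted slope strictly monotone over the PMA grid."""
        means = []
        for pma in (27, 31, 35, 39, 43, 47):
            vals = []
            for s in range(3):
                cfg = _cfg(pma_weeks=pma, duration_min=5, seed=40 + s)
                rec, _ = generate_recording(cfg)
                segs = normalize(segment(preprocess(derive_bipolar(rec))))
                vals.append(embed_segments(segs.data.reshape(-1, 1920))[:, 10].mean())
            means.append(np.mean(vals))
        assert np.all(np.diff(means) > 0)

    def test_qs_discontinuous_as_continuous(self):
        """QS 3-s-window SDs spread burst-vs-trough; AS stays unimodal."""
        cfg = _cfg(pma_weeks=29, duration_min=60, seed=2)
        rng = np.random.default_rng(cfg.seed)
        hyp = sample_hypnogram(cfg, rng)
        rec, truth = synthesize_eeg(cfg, hyp, rng)
        segs = normalize(segment(preprocess(derive_bipolar(rec))))
        emb = embed_segments(segs.data.transpose(1, 0, 2).reshape(-1, 1920))
        ratio = emb[:, 11].reshape(segs.n_segments, segs.n_channels).mean(axis=1)
        qs = np.asarray([s == "QS" for s in hyp[: segs.n_segments]])
        as_ = np.asarray([s == "AS" for s in hyp[: segs.n_segments]])
        assert qs.any() and as_.any()
        # burst/trough modulation: p90/p10 window-SD ratio clearly larger in QS
        assert ratio[qs].mean() > 2 * ratio[as_].mean()

    def test_stage_separability_with_threshold_oracle(self):
        """A single variance-modulation threshold detects QS at >= 90 %."""
        scores, labels = [], []
        for s in range(3):
            cfg = _cfg(pma_weeks=33 + 4 * s, duration_min=60, seed=60 + s)
            rng = np.random.default_rng(cfg.seed)
            hyp = sample_hypnogram(cfg, rng)
            rec, _ = synthesize_eeg(cfg, hyp, rng)
            segs = normalize(segment(preprocess(derive_bipolar(rec))))
            emb = embed_segments(segs.data.transpose(1, 0, 2).reshape(-1, 1920))
            ratio = emb[:, 11].reshape(segs.n_segments, segs.n_channels).mean(axis=1)
            scores.extend(ratio)
            labels.extend(s == "QS" for s in hyp[: segs.n_segments])
        scores, labels = np.asarray(scores), np.asarray(labels)
        thr = (scores[labels].mean() + scores[~labels].mean()) / 2
        acc = ((scores > thr) == labels).mean()
        assert acc >= 0.90

    def test_wake_has_beta_excess(self):
        cfg = _cfg(pma_weeks=40, duration_min=120, seed=9)
        rng = np.random.default_rng(cfg.seed)
        hyp = sample_hypnogram(cfg, rng)
        assert any(s == "wake" for s in hyp)
        rec, _ = synthesize_eeg(cfg, hyp, rng)
        segs = normalize(segment(preprocess(derive_bipolar(rec))))
        emb = embed_segments(segs.data.transpose(1, 0, 2).reshape(-1, 1920))
        rel_hi = emb[:, 13].reshape(segs.n_segments, segs.n_channels).mean(axis=1)
        wake = np.asarray([s == "wake" for s in hyp[: segs.n_segments]])
        as_ = np.asarray([s == "AS" for s in hyp[: segs.n_segments]])
        assert rel_hi[wake].mean() > rel_hi[as_].mean()

    def test_zero_duration_edge(self):
        cfg = _cfg(duration_min=0.0)
        rng = np.random.default_rng(0)
        hyp = sample_hypnogram(cfg, rng)
        rec, truth = synthesize_eeg(cfg, hyp, rng)
        assert rec.n_samples == 0
        assert len(truth.hypnogram) == 0

    def test_full_determinism(self):
        cfg = _cfg(duration_min=5, artifact_rate=0.3, novelty_rate=0.05)
        r1, t1 = generate_recording(cfg)
        r2, t2 = generate_recording(cfg)
        assert np.array_equal(r1.signals, r2.signals)
        assert np.array_equal(t1.artifact_mask, t2.artifact_mask)
        assert np.array_equal(t1.novelty_mask, t2.novelty_mask)


class TestInjectArtifacts:
    def test_zero_rate_is_identity(self):
        cfg = _cfg(duration_min=5)
        rng = np.random.default_rng(1)
        hyp = sample_hypnogram(cfg, rng)
        rec, truth = synthesize_eeg(cfg, hyp, rng)
        out, t2 = inject_artifacts(rec, truth, cfg, rng)
        assert np.array_equal(out.signals, rec.signals)
        assert not t2.artifact_mask.any()

    def test_affected_epoch_fraction_binomial(self):
        cfg = _cfg(duration_min=100, artifact_rate=0.3, seed=4)  # 200 epochs
        rec, truth = generate_recording(cfg)
        spe = int(30 * rec.fs)
        n_ep = len(truth.hypnogram)
        affected = truth.artifact_mask.reshape(rec.n_channels, n_ep, spe).any(axis=(0, 2))
        assert 0.23 <= affected.mean() <= 0.37

    def test_signal_untouched_outside_mask(self):
        cfg = _cfg(duration_min=10, artifact_rate=0.4, seed=6)
        rng = np.random.default_rng(cfg.seed)
        hyp = sample_hypnogram(cfg, rng)
        rec, truth = synthesize_eeg(cfg, hyp, rng)
        out, t2 = inject_artifacts(rec, truth, cfg, rng)
        outside = ~t2.artifact_mask
        assert np.array_equal(out.signals[outside], rec.signals[outside])

    def test_movement_events_are_high_amplitude(self):
        cfg = _cfg(duration_min=30, artifact_rate=0.5, seed=7)
        rng = np.random.default_rng(cfg.seed)
        hyp = sample_hypnogram(cfg, rng)
        rec, truth = synthesize_eeg(cfg, hyp, rng)
        out, t2 = inject_artifacts(rec, truth, cfg, rng)
        # pooled: artifact samples have clearly higher RMS than background
        art = t2.artifact_mask
        assert art.any()
        rms_art = np.sqrt((out.signals[art] ** 2).mean())
        rms_bg = np.sqrt((out.signals[~art] ** 2).mean())
        assert rms_art > 2.0 * rms_bg


class TestInjectNovelties:
    def test_zero_rate_is_identity(self):
        cfg = _cfg(duration_min=5)
        rec, truth = generate_recording(cfg)
        rng = np.random.default_rng(9)
        out, t2 = inject_novelties(rec, truth, cfg, rng)
        assert np.array_equal(out.signals, rec.signals)

    def test_narrowband_replacement_power_concentration(self):
        cfg = _cfg(duration_min=30, novelty_rate=0.15, seed=10)
        rec, truth = generate_recording(cfg)
        spe = int(30 * rec.fs)
        found = False
        for ch, e in zip(*np.nonzero(truth.novelty_mask)):
            x = rec.signals[ch, e * spe : (e + 1) * spe]
            f = np.fft.rfftfreq(spe, 1 / rec.fs)
            p = np.abs(np.fft.rfft(x)) ** 2
            band = (f >= 19.0) & (f <= 21.0)
            if p[band].sum() / p.sum() > 0.7:
                found = True
                break
        assert found, "no narrowband novelty with >70 % power in a 2-Hz band"

    def test_mask_determinism(self):
        cfg = _cfg(duration_min=10, novelty_rate=0.1, seed=11)
        _, t1 = generate_recording(cfg)
        _, t2 = generate_recording(cfg)
        assert np.array_equal(t1.novelty_mask, t2.novelty_mask)


class TestFixtureIO:
    def test_round_trip(self, tmp_path):
        cfg = _cfg(duration_min=3, artifact_rate=0.3, novelty_rate=0.1, seed=12)
        rec, truth = generate_recording(cfg)
        write_fixture(rec, truth, tmp_path, cfg)
        rec2, truth2 = load_fixture(tmp_path)
        bound = np.ceil(np.abs(rec.signals).max()) / 2**15
        assert np.abs(rec2.signals - rec.signals).max() <= bound + 1e-9
        assert list(truth2.hypnogram) == list(truth.hypnogram)
        assert np.array_equal(truth2.artifact_mask, truth.artifact_mask)
        assert np.array_equal(truth2.novelty_mask, truth.novelty_mask)
        assert truth2.pma_weeks == truth.pma_weeks

    def test_meta_echoes_config(self, tmp_path):
        cfg = _cfg(duration_min=1, seed=13)
        rec, truth = generate_recording(cfg)
        write_fixture(rec, truth, tmp_path, cfg)
        meta = json.loads((tmp_path / "meta.json").read_text())
        assert meta["seed"] == 13
        assert meta["config"]["pma_weeks"] == 35
        hyp_lines = (tmp_path / "hypnogram.csv").read_text().strip().splitlines()
        assert len(hyp_lines) - 1 == len(truth.hypnogram)


class TestDerivationMasks:
    def test_or_of_electrode_masks(self):
        cfg = _cfg(duration_min=2, artifact_rate=0.5, seed=14)
        rec, truth = generate_recording(cfg)
        pairs = (("C3", "C4"), ("C3", "Cz"))
        art64, nov = derivation_masks(truth, rec.channel_labels, "Cz", pairs, rec.fs)
        idx = {c: i for i, c in enumerate(rec.channel_labels)}
        ref_mask = truth.artifact_mask[idx["C3"]] | truth.artifact_mask[idx["C4"]]
        n64 = art64.shape[1]
        expected = ref_mask[: n64 * 4].reshape(n64, 4).any(axis=1)
        assert np.array_equal(art64[0], expected)
        # C3-Cz: reference contributes nothing
        ref_mask_c3 = truth.artifact_mask[idx["C3"]]
        expected_c3 = ref_mask_c3[: n64 * 4].reshape(n64, 4).any(axis=1)
        assert np.array_equal(art64[1], expected_c3)
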