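"""The three reliability criteria and their decision boundaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoeeg.errors import CalibrationError
from neoeeg.quality_control import (
    QCThresholds,
    SegmentFlags,
    artifact_fraction,
    calibrate_attention_threshold,
    combine_flags,
    detect_novelties,
    fit_novelty_model,
    flag_artifact,
    flag_uncertain,
    majority_novelty,
    spectral_features,
    spectral_features_batch,
)

THR = QCThresholds(attention_min=0.5)


class TestArtifactCriterion:
    def test_fraction_pooled_over_channels(self):
        m = np.zeros((2, 1920), bool)
        m[0] = True  # 100 %
        m[1, : 1920 // 5] = True  # 20 %
        assert artifact_fraction(m) == pytest.approx(0.6)

    def test_all_false_is_zero(self):
        assert artifact_fraction(np.zeros((3, 1920), bool)) == 0.0

    @pytest.mark.parametrize(
        "fraction,flagged", [(0.0, False), (0.5, False), (0.51, True), (1.0, True)]
    )
    def test_strict_majority_boundary(self, fraction, flagged):
        assert flag_artifact(fraction, THR) is flagged

    def test_fraction_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            n_ch = rng.integers(1, 6)
            n = rng.integers(10, 200)
            m = rng.random((n_ch, n)) < rng.random()
            brute = sum(int(v) for row in m for v in row) / (n_ch * n)
            assert artifact_fraction(m) == pytest.approx(brute)


class TestSpectralFeatures:
    def test_pure_delta_tone(self):
        t = np.arange(1920) / 64.0
        f, degen = spectral_features(np.sin(2 * np.pi * 2.0 * t))
        assert not degen
        assert f[0] > 0.95  # delta relative power
        assert f[6] < 4.0  # SEF95

    def test_white_noise_high_entropy(self):
        x = np.random.default_rng(1).standard_normal(1920)
        f, degen = spectral_features(x)
        assert f[7] > 0.9

    def test_zero_input_sentinel(self):
        f, degen = spectral_features(np.zeros(1920))
        assert degen
        assert f[8] == -12.0 and f[7] == 0.0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariants_on_random_signals(self, seed):
        x = np.random.default_rng(seed).standard_normal(1920)
        f, _ = spectral_features(x)
        assert np.all(f[:4] >= 0) and f[:4].sum() <= 1 + 1e-6
        assert f[4] <= f[5] <= f[6]  # SEF75 <= SEF90 <= SEF95
        assert 0.0 <= f[7] <= 1.0


class TestNovelty:
    def test_majority_rule_boundaries(self):
        assert majority_novelty([True, True, True, False, False])  # 3 of 5
        assert not majority_novelty([True, True, False, False, False])  # 2 of 5
        assert not majority_novelty([False] * 5)

    def test_majority_rule_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(500):
            flags = rng.random(rng.integers(1, 12)) < rng.random()
            brute = sum(bool(f) for f in flags) > len(flags) / 2
            assert majority_novelty(flags) == brute

    def test_fit_requires_enough_samples(self):
        with pytest.raises(CalibrationError):
            fit_novelty_model(np.zeros((100, 9)), task="fba")

    def test_refit_same_seed_same_decisions(self):
        rng = np.random.default_rng(3)
        feats = rng.standard_normal((600, 9))
        probe = rng.standard_normal((50, 9))
        m1 = fit_novelty_model(feats, "fba", seed=5)
        m2 = fit_novelty_model(feats, "fba", seed=5)
        assert np.array_equal(m1.decision(probe), m2.decision(probe))

    def test_inlier_false_positive_rate_bounded(self, small_bundle, clean_recording):
        """Hold-out inliers flagged at <= 7 % with contamination 0.05."""
        from neoeeg.pipeline import prepare_segments

        (rec, _), _ = clean_recording
        segs = prepare_segments(rec)
        x = segs.data.transpose(1, 0, 2).reshape(-1, 1920)
        feats, _ = spectral_features_batch(x)
        flags = small_bundle.novelty_models["fba"].decision(feats)
        assert flags.mean() <= 0.07

    def test_synthetic_novelties_detected(self, small_bundle):
        """Narrowband / white / spike-train epochs flagged at >= 90 %."""
        from neoeeg.pipeline import prepare_segments
        from neoeeg.synthetic_data import (
            GenerationConfig,
            derivation_masks,
            generate_recording,
        )

        cfg = GenerationConfig(
            pma_weeks=36, duration_min=40, seed=303, artifact_rate=0.0, novelty_rate=0.3
        )
        rec, truth = generate_recording(cfg)
        segs = prepare_segments(rec)
        _, nov = derivation_masks(
            truth, rec.channel_labels, rec.reference_label, small_bundle.pairs, rec.fs
        )
        x = segs.data.transpose(1, 0, 2).reshape(-1, 1920)
        feats, _ = spectral_features_batch(x)
        flags = small_bundle.novelty_models["fba"].decision(feats)
        flags = flags.reshape(segs.n_segments, segs.n_channels).T
        truth_flags = nov[:, : segs.n_segments]
        assert truth_flags.any()
        sensitivity = flags[truth_flags].mean()
        assert sensitivity >= 0.90

    def test_detect_novelties_segment_rule(self):
        rng = np.random.default_rng(4)
        feats = rng.standard_normal((600, 9))
        model = fit_novelty_model(feats, "fba", seed=1)
        # far-out features: all channels novel -> segment flagged
        probe = np.full((5, 9), 50.0)
        ch_flags, seg_flag = detect_novelties(model, probe)
        assert ch_flags.all() and seg_flag


class TestUncertainty:
    def test_percentile_of_uniform_calibration(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1, 1000)
        thr = calibrate_attention_threshold(vals)
        assert 0.005 <= thr <= 0.02

    def test_constant_calibration_values(self):
        assert calibrate_attention_threshold(np.full(200, 5.0)) == 5.0

    def test_calibration_set_self_flag_rate(self):
        rng = np.random.default_rng(6)
        vals = rng.lognormal(0, 1, 500)
        thr_obj = QCThresholds(attention_min=calibrate_attention_threshold(vals))
        flagged = np.mean([flag_uncertain(v, None, thr_obj, "fba") for v in vals])
        assert flagged <= 0.01 + 1.0 / len(vals)

    def test_too_few_calibration_values(self):
        with pytest.raises(CalibrationError):
            calibrate_attention_threshold(np.ones(50))

    def test_attention_rule_applies_to_both_tasks(self):
        assert flag_uncertain(0.4, 0.95, THR, "fba")
        assert flag_uncertain(0.4, 0.95, THR, "sleep")

    def test_qs_probability_band_sleep_only(self):
        assert flag_uncertain(10.0, 0.55, THR, "sleep")
        assert not flag_uncertain(10.0, 0.55, THR, "fba")
        assert not flag_uncertain(10.0, 0.95, THR, "sleep")

    def test_uncalibrated_threshold_rejected(self):
        with pytest.raises(CalibrationError):
            flag_uncertain(1.0, None, QCThresholds(), "fba")


class TestCombineFlags:
    @pytest.mark.parametrize(
        "a,n,u,expected",
        [
            (False, False, False, False),
            (True, False, False, True),
            (False, True, False, True),
            (False, False, True, True),
            (True, True, True, True),
        ],
    )
    def test_reject_is_or(self, a, n, u, expected):
        assert combine_flags(a, n, u).reject is expected

    def test_criteria_independent(self):
        """Forcing one criterion never alters another's stored value."""
        f1 = combine_flags(True, False, False)
        f2 = combine_flags(True, True, False)
        assert f1.artifact == f2.artifact
        assert f1.uncertain == f2.uncertain


class TestNonInterference:
    def test_qc_never_modifies_predictions(self, small_bundle, heldout_recording):
        """Retained segments' outputs are identical with QC on or off."""
        from neoeeg.pipeline import analyze, prepare_segments

        (rec, _), _ = heldout_recording
        segs = prepare_segments(rec)
        _, agg_raw = small_bundle.model.predict_recording(segs)
        result = analyze(small_bundle, rec)
        for s in range(result.n_segments):
            if result.flags["fba"][s].reject:
                continue
            if result.flags["fba"][s].channel_novelty.any():
                continue  # exclusion re-weights by design
            assert result.aggregated[s].fba_weeks == pytest.approx(
                agg_raw[s].fba_weeks
            )


class TestRejectionBehaviour:
    def test_clean_recording_low_rejection(self, small_bundle, clean_recording):
        from neoeeg.pipeline import analyze

        (rec, _), _ = clean_recording
        result = analyze(small_bundle, rec)
        assert result.qc_summary["fba"]["rejected_fraction"] <= 0.05

    def test_artifact_criterion_dominates_with_artifact_injections(self, small_bundle):
        """With heavy artifact injection the artifact flag is the most
        frequent criterion and drives the rejection increase."""
        from neoeeg.pipeline import analyze
        from neoeeg.synthetic_data import GenerationConfig, generate_recording

        cfg = GenerationConfig(
            pma_weeks=34, duration_min=60, seed=777, artifact_rate=0.3, novelty_rate=0.0
        )
        rec, _ = generate_recording(cfg)
        result = analyze(small_bundle, rec)
        s = result.qc_summary["fba"]
        assert s["rejected_fraction"] > 0.05
        assert s["artifact_fraction"] >= s["novelty_fraction"]
        assert s["artifact_fraction"] >= s["uncertain_fraction"]
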