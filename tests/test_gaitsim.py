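"""Structural and statistical contracts of the synthetic gait generator."""

from __future__ import annotations

import numpy as np
import pytest

from gaitnet.gaitsim import (
    ACTIVITY_TEMPLATES, CYCLE_PARAMS_S, DURATION_PARAMS_S, GaitSimConfig,
    _trial_rng, effective_template, iter_trials, sample_duration,
    simulate_dataset, simulate_trial,
)
from gaitnet.signals import ACTIVITIES, DatasetManifest, read_recording
from gaitnet.windowing import WINDOW_SECONDS


class TestTrialStructure:
    def test_shapes_rates_and_duration_agreement(self):
        cfg = GaitSimConfig(n_subjects=10, seed=1)
        emg, robot = simulate_trial("S0003", "RA", 2, cfg)
        assert emg.samples.shape[1] == 8
        assert robot.samples.shape[1] == 7
        assert emg.sampling_rate_hz == 2000.0
        assert robot.sampling_rate_hz == pytest.approx(71.42857)
        # both modalities span the same time within one robot sample period
        assert abs(emg.duration_s - robot.duration_s) <= 1.0 / robot.sampling_rate_hz
        assert np.isfinite(emg.samples).all() and np.isfinite(robot.samples).all()

    def test_duration_never_below_one_window(self):
        cfg = GaitSimConfig(n_subjects=10, seed=2,
                            duration_params_s={a: (1.0, 2.0) for a in ACTIVITIES})
        rng = np.random.default_rng(0)
        durations = [sample_duration("LW", cfg, rng) for _ in range(500)]
        assert min(durations) >= WINDOW_SECONDS

    def test_determinism_per_trial_key(self):
        cfg = GaitSimConfig(n_subjects=10, seed=5)
        a1, r1 = simulate_trial("S0004", "SD", 3, cfg)
        a2, r2 = simulate_trial("S0004", "SD", 3, cfg)
        assert np.array_equal(a1.samples, a2.samples)
        assert np.array_equal(r1.samples, r2.samples)
        a3, _ = simulate_trial("S0004", "SD", 2, cfg)
        assert a3.samples.shape != a1.samples.shape or not np.array_equal(
            a3.samples, a1.samples)

    def test_angle_channels_bounded(self):
        cfg = GaitSimConfig(n_subjects=10, seed=6)
        for activity in ACTIVITIES:
            tpl = effective_template(activity, cfg.class_separation)
            _, robot = simulate_trial("S0005", activity, 1, cfg)
            for ch in (0, 1):
                dev = np.abs(robot.samples[:, ch] - tpl.hip_offset_deg)
                # subject gain is Normal(1, 0.05); 1.5 covers 10 sigma
                assert dev.max() <= tpl.hip_amplitude_deg * 1.5 + 3 * cfg.noise_sd

    def test_invalid_inputs(self):
        cfg = GaitSimConfig(n_subjects=10)
        with pytest.raises(ValueError):
            simulate_trial("S0001", "JUMP", 1, cfg)
        with pytest.raises(ValueError):
            GaitSimConfig(noise_sd=0.0)
        with pytest.raises(ValueError):
            GaitSimConfig(class_separation=-0.5)


class TestSeparation:
    def test_zero_separation_collapses_templates(self):
        templates = [effective_template(a, 0.0) for a in ACTIVITIES]
        first = templates[0]
        for tpl in templates[1:]:
            assert tpl.hip_amplitude_deg == pytest.approx(first.hip_amplitude_deg)
            assert tpl.pitch_offset_deg == pytest.approx(first.pitch_offset_deg)
            assert tpl.burst_gains == pytest.approx(first.burst_gains)

    def test_full_separation_recovers_configured_templates(self):
        for a in ACTIVITIES:
            assert effective_template(a, 1.0) == ACTIVITY_TEMPLATES[a]

    def test_classifier_quality_is_monotone_in_separation(self):
        """Held-out macro F of a fixed cheap classifier does not decrease as
        class separation grows."""
        from sklearn.linear_model import LogisticRegression
        from gaitnet.fit_eval import metrics_from_confusion, confusion_matrix
        from tests.conftest import build_robot_splits

        scores = []
        for sep in (0.0, 0.5, 1.0):
            splits = build_robot_splits(n_subjects=10, class_separation=sep,
                                        sim_seed=21, split_seed=1)
            tr, te = splits["train"]["robot"], splits["test"]["robot"]
            feats = lambda ws: np.concatenate(  # noqa: E731
                [ws.windows.mean(axis=1), ws.windows.std(axis=1)], axis=1)
            clf = LogisticRegression(max_iter=500)
            clf.fit(feats(tr), tr.labels)
            cm = confusion_matrix(te.labels, clf.predict(feats(te)))
            scores.append(metrics_from_confusion(cm).f_measure_macro)
        assert scores[0] <= scores[1] + 0.05
        assert scores[1] <= scores[2] + 0.05
        assert scores[2] - scores[0] > 0.3
        assert scores[0] < 0.45  # near chance without separation


class TestCalibration:
    def test_per_activity_duration_means(self):
        """Empirical duration means track the configured per-activity means
        within 3 standard errors at 1,000 draws per activity."""
        cfg = GaitSimConfig(n_subjects=500, seed=9)
        rng = np.random.default_rng(123)
        for activity, (mean, sd) in DURATION_PARAMS_S.items():
            draws = np.array([sample_duration(activity, cfg, rng)
                              for _ in range(1000)])
            se = draws.std() / np.sqrt(len(draws))
            assert abs(draws.mean() - mean) <= 3 * se + 0.02  # small clamp bias

    def test_cycle_periods_are_activity_specific(self):
        cfg = GaitSimConfig(n_subjects=10, seed=10)
        from gaitnet.gaitsim import sample_cycle_period
        rng = np.random.default_rng(7)
        means = {a: np.mean([sample_cycle_period(a, cfg, rng) for _ in range(800)])
                 for a in ACTIVITIES}
        for a, (mean, sd) in CYCLE_PARAMS_S.items():
            assert abs(means[a] - mean) <= 3 * sd / np.sqrt(800) + 0.02


class TestDataset:
    def test_dataset_layout_and_round_trip(self, tmp_path):
        cfg = GaitSimConfig(n_subjects=10, seed=13)
        manifest, summary = simulate_dataset(cfg, tmp_path, modalities=("robot",))
        assert len(manifest.entries) == 10 * 5 * 3
        assert summary["n_trials"] == 150
        back = DatasetManifest.from_json(tmp_path / "manifest.json")
        entry = back.entries[0]
        rec = read_recording(tmp_path / entry.path, entry)
        assert rec.samples.shape[1] == 7

    def test_trial_enumeration(self):
        cfg = GaitSimConfig(n_subjects=12)
        trials = list(iter_trials(cfg))
        assert len(trials) == 12 * 5 * 3
        assert trials[0] == ("S0001", "LW", 1)

    def test_too_few_subjects_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            simulate_dataset(GaitSimConfig(n_subjects=5), tmp_path)

    def test_seeded_rerun_is_identical(self, tmp_path):
        cfg = GaitSimConfig(n_subjects=10, seed=17)
        simulate_dataset(cfg, tmp_path / "a", modalities=("robot",))
        simulate_dataset(cfg, tmp_path / "b", modalities=("robot",))
        f = "S0002_SA_t1_robot.csv"
        assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_trial_rng_is_order_independent(self):
        cfg = GaitSimConfig(n_subjects=10, seed=4)
        r1 = _trial_rng(cfg, "S0007", "RD", 2).normal(size=3)
        _ = _trial_rng(cfg, "S0001", "LW", 1).normal(size=3)
        r2 = _trial_rng(cfg, "S0007", "RD", 2).normal(size=3)
        assert np.array_equal(r1, r2)
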