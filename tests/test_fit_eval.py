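"""Training protocol (plateau decay, checkpointing) and confusion metrics."""

from __future__ import annotations

import numpy as np
import pytest

from gaitnet.fit_eval import (
    TrainConfig, confusion_matrix, encode_labels, metrics_from_confusion,
    one_vs_rest_counts, row_normalized, train_model,
)
from gaitnet.nn import Dense, Flatten, Network, PlateauScheduler, ReLU
from gaitnet.signals import ACTIVITIES
from gaitnet.windowing import WindowSet


def tiny_windowset(windows, labels, subjects=None):
    n = windows.shape[0]
    subjects = subjects if subjects is not None else np.array(["A"] * n)
    return WindowSet(modality="robot", windows=windows.astype(np.float32),
                     labels=np.asarray(labels), subject_ids=np.asarray(subjects),
                     start_indices=np.zeros(n, dtype=int),
                     trial_keys=np.array([f"A/LW/{i}" for i in range(n)]))


class TestPlateauScheduler:
    def test_schedule_arithmetic_when_loss_never_improves(self):
        """Val loss improving only at epoch 1: the LR in force at epoch 21 is
        0.9x the initial rate and at epoch 31 it is 0.81x."""
        lr0 = 1e-3
        sched = PlateauScheduler(lr0, factor=0.9, patience=10)
        lr_in_force = {}
        current = lr0
        for epoch in range(1, 41):
            lr_in_force[epoch] = current
            current = sched.update(1.0 if epoch == 1 else 2.0)
        assert lr_in_force[11] == pytest.approx(lr0)
        assert lr_in_force[21] == pytest.approx(lr0 * 0.9)
        assert lr_in_force[31] == pytest.approx(lr0 * 0.81)

    def test_counter_resets_on_improvement(self):
        sched = PlateauScheduler(1.0, factor=0.5, patience=3)
        for loss in (5.0, 6.0, 4.0, 6.0, 6.0):  # improvement at loss=4.0
            lr = sched.update(loss)
        assert lr == 1.0
        assert sched.update(6.0) == 0.5  # third bad epoch after the best

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            PlateauScheduler(1.0, factor=1.5)
        with pytest.raises(ValueError):
            TrainConfig(plateau_patience=0)


class TestTraining:
    def _toy_model(self, rng, n_classes):
        return Network(
            heads=[("robot", [Flatten(), Dense(10 * 2, 16, rng=rng), ReLU()])],
            trunk=[Dense(16, n_classes, rng=rng)], n_classes=n_classes)

    def _separable_data(self, rng, n=32):
        windows = rng.normal(size=(n, 10, 2)) * 0.1
        labels = np.array((["LW"] * (n // 2)) + (["SA"] * (n - n // 2)))
        windows[labels == "SA"] += 1.0
        return tiny_windowset(windows, labels)

    def test_overfits_separable_two_class_toy(self, rng):
        """32 separable windows reach training accuracy 1.0 within the
        protocol's 200-epoch budget."""
        ws = self._separable_data(rng)
        model = self._toy_model(rng, n_classes=5)
        cfg = TrainConfig(initial_lr=1e-3, batch_size=8, max_epochs=200, seed=0)
        model, history = train_model(model, ws, ws, cfg)
        assert max(history["acc"]) == 1.0

    def test_checkpoint_is_argmin_val_loss(self, rng):
        from gaitnet.nn import evaluate_loss_acc
        from gaitnet.fit_eval import to_arrays
        tr = self._separable_data(rng, n=48)
        val = self._separable_data(np.random.default_rng(5), n=24)
        model = self._toy_model(rng, n_classes=5)
        cfg = TrainConfig(initial_lr=1e-3, batch_size=8, max_epochs=25, seed=1)
        model, history = train_model(model, tr, val, cfg)
        assert history["checkpoint_epoch"] == int(np.argmin(history["val_loss"]))
        xv, yv = to_arrays(val)
        restored_loss, _ = evaluate_loss_acc(model, xv, yv)
        assert restored_loss <= history["val_loss"][-1] + 1e-9
        assert restored_loss == pytest.approx(min(history["val_loss"]), abs=1e-9)

    def test_empty_training_set_rejected(self, rng):
        ws = tiny_windowset(np.empty((0, 10, 2)), np.array([], dtype="<U2"))
        model = self._toy_model(rng, 5)
        with pytest.raises(ValueError):
            train_model(model, ws, ws, TrainConfig(max_epochs=1))


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array(["LW", "SA", "SD", "RA", "RD"] * 4)
        cm = confusion_matrix(y, y)
        assert np.array_equal(cm, np.diag([4] * 5))

    def test_single_predicted_class_fills_one_column(self):
        y_true = np.array(["LW", "SA", "SD", "RA", "RD"])
        y_pred = np.array(["LW"] * 5)
        cm = confusion_matrix(y_true, y_pred)
        assert cm[:, 0].sum() == 5
        assert cm[:, 1:].sum() == 0

    def test_permutation_invariance(self, rng):
        y_true = rng.integers(0, 5, 100)
        y_pred = rng.integers(0, 5, 100)
        perm = rng.permutation(100)
        assert np.array_equal(confusion_matrix(y_true, y_pred),
                              confusion_matrix(y_true[perm], y_pred[perm]))

    def test_label_outside_class_set(self):
        with pytest.raises(ValueError):
            confusion_matrix(np.array(["LW", "FLY"]), np.array(["LW", "LW"]))
        with pytest.raises(ValueError):
            confusion_matrix(np.array([0, 7]), np.array([0, 0]))

    def test_row_normalized_percentages(self):
        cm = np.array([[8, 2], [0, 0]])
        rn = row_normalized(cm)
        assert np.allclose(rn[0], [80.0, 20.0])
        assert np.allclose(rn[1], [0.0, 0.0])


class TestMetrics:
    def test_identity_confusion_gives_perfect_metrics(self):
        rep = metrics_from_confusion(np.diag([10, 20, 30, 5, 5]))
        assert rep.accuracy == 1.0
        assert rep.recall_macro == rep.precision_macro == rep.f_measure_macro == 1.0
        assert rep.recall_sd == rep.precision_sd == rep.f_measure_sd == 0.0

    def test_binary_hand_computed_example(self):
        rep = metrics_from_confusion(np.array([[8, 2], [1, 9]]))
        assert rep.recall_per_class[0] == pytest.approx(0.8)
        assert rep.precision_per_class[0] == pytest.approx(8 / 9)
        expected_f = 2 * 0.8 * (8 / 9) / (0.8 + 8 / 9)
        assert rep.f_measure_per_class[0] == pytest.approx(expected_f, abs=1e-4)
        assert rep.f_measure_per_class[0] == pytest.approx(0.8421, abs=1e-4)

    def test_macro_f_bounded_by_per_class_extremes(self, rng):
        cm = rng.integers(0, 30, size=(5, 5))
        cm[0, 0] += 10
        rep = metrics_from_confusion(cm)
        assert min(rep.f_measure_per_class) <= rep.f_measure_macro
        assert rep.f_measure_macro <= max(rep.f_measure_per_class)

    def test_empty_class_conventions(self):
        cm = np.zeros((3, 3), dtype=int)
        cm[0, 0] = 5
        cm[1, 0] = 3   # class 1 never predicted correctly, class 2 absent
        rep = metrics_from_confusion(cm)
        assert rep.recall_per_class[1] == 0.0
        assert rep.precision_per_class[2] == 0.0   # never predicted
        assert rep.recall_per_class[2] == 0.0      # no true instances

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(np.zeros((5, 5)))

    def test_one_vs_rest_rows_sum_to_total(self, rng):
        cm = rng.integers(0, 50, size=(5, 5))
        counts = one_vs_rest_counts(cm)
        assert np.all(counts.sum(axis=1) == cm.sum())

    def test_metrics_match_brute_force_label_enumeration(self, rng):
        """Oracle: recompute TP/FP/FN/TN per class by explicit comparison of
        random label vectors, apply the four formulas directly, and compare
        with the confusion-matrix route (200 random cases)."""
        for _ in range(200):
            n = int(rng.integers(5, 80))
            k = int(rng.integers(2, 6))
            y_true = rng.integers(0, k, n)
            y_pred = rng.integers(0, k, n)
            cm = confusion_matrix(y_true, y_pred, n_classes=k)
            rep = metrics_from_confusion(cm)
            recalls, precisions, fs = [], [], []
            for c in range(k):
                tp = int(np.sum((y_true == c) & (y_pred == c)))
                fp = int(np.sum((y_true != c) & (y_pred == c)))
                fn = int(np.sum((y_true == c) & (y_pred != c)))
                tn = int(np.sum((y_true != c) & (y_pred != c)))
                assert tp + fp + fn + tn == n
                r = tp / (tp + fn) if tp + fn else 0.0
                p = tp / (tp + fp) if tp + fp else 0.0
                recalls.append(r)
                precisions.append(p)
                fs.append(2 * p * r / (p + r) if p + r else 0.0)
            assert rep.accuracy == pytest.approx(np.mean(y_true == y_pred))
            assert rep.recall_per_class == pytest.approx(recalls)
            assert rep.precision_per_class == pytest.approx(precisions)
            assert rep.f_measure_per_class == pytest.approx(fs)
            assert rep.recall_sd == pytest.approx(np.std(recalls))

    def test_accuracy_equals_support_weighted_recall(self, rng):
        cm = rng.integers(0, 40, size=(5, 5))
        cm += np.diag(rng.integers(1, 10, 5))
        rep = metrics_from_confusion(cm)
        support = cm.sum(axis=1)
        weighted = np.sum(np.array(rep.recall_per_class) * support) / support.sum()
        assert rep.accuracy == pytest.approx(weighted)

    def test_label_encoding_follows_canonical_order(self):
        assert list(encode_labels(np.array(ACTIVITIES))) == [0, 1, 2, 3, 4]
        with pytest.raises(ValueError):
            encode_labels(np.array(["XX"]))
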