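"""Final-model training protocol and confusion-matrix metrics.

Training follows the study protocol: Adam with categorical cross-entropy,
up to 200 epochs, the learning rate multiplied by 0.9 whenever the
validation loss fails to improve for 10 consecutive epochs, and the weights
of the minimum-validation-loss epoch kept.

Metrics are the four confusion-matrix statistics — accuracy, recall,
precision and F-measure — computed one-vs-rest per class and summarized as
the macro mean with the across-class standard deviation in parentheses
(e.g. "0.9606 (0.04)").  Accuracy is primarily micro (trace/total); the
mean per-class one-vs-rest accuracy is reported alongside.  A class with no
predicted (true) instances gets precision (recall) 0, logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .nn import Network, fit
from .signals import ACTIVITIES
from .windowing import WindowSet

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Adam + plateau-decay training protocol."""

    initial_lr: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 200
    plateau_factor: float = 0.9
    plateau_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must be in (0, 1)")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be >= 1")


def encode_labels(labels: np.ndarray) -> np.ndarray:
    """Activity strings -> integer class ids in canonical LW/SA/SD/RA/RD order."""
    lut = {a: i for i, a in enumerate(ACTIVITIES)}
    try:
        return np.array([lut[str(l)] for l in labels], dtype=int)
    except KeyError as exc:
        raise ValueError(f"label outside the activity set: {exc}") from None


def to_arrays(data) -> tuple:
    """WindowSet (or dict of aligned WindowSets) -> (X, y_int)."""
    if isinstance(data, WindowSet):
        return data.windows.astype(np.float64), encode_labels(data.labels)
    if isinstance(data, dict):
        xs = {m: ws.windows.astype(np.float64) for m, ws in data.items()}
        labels = [encode_labels(ws.labels) for ws in data.values()]
        for a, b in zip(labels, labels[1:]):
            if not np.array_equal(a, b):
                raise ValueError("modalities are not index-aligned")
        return xs, labels[0]
    raise TypeError("expected a WindowSet or a dict of WindowSets")


def train_model(model: Network, train_data, val_data, cfg: TrainConfig,
                verbose: bool = False) -> tuple[Network, dict]:
    """Train with the plateau/checkpoint protocol; returns (model, history).

    The returned model carries the weights of the epoch with the lowest
    validation loss; history records per-epoch train/val loss and accuracy
    and the learning-rate trace.
    """
    x, y = to_arrays(train_data)
    xv, yv = to_arrays(val_data)
    history = fit(
        model, x, y, x_val=xv, y_val=yv,
        epochs=cfg.max_epochs, batch_size=cfg.batch_size, lr=cfg.initial_lr,
        plateau_factor=cfg.plateau_factor, plateau_patience=cfg.plateau_patience,
        checkpoint_best=True, rng=np.random.default_rng(cfg.seed), verbose=verbose)
    return model, history


def history_to_csv(history: dict, path: str | Path) -> None:
    cols = {k: v for k, v in history.items() if isinstance(v, list)}
    pd.DataFrame(cols).to_csv(path, index_label="epoch")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def confusion_matrix(y_true, y_pred, n_classes: int = len(ACTIVITIES)) -> np.ndarray:
    """Entry (i, j) = count of true class i predicted as class j.

    Accepts integer class ids or activity strings.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if y_true.dtype.kind in "US":
        y_true = encode_labels(y_true)
    if y_pred.dtype.kind in "US":
        y_pred = encode_labels(y_pred)
    for arr in (y_true, y_pred):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError("label outside the class set")
    return _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))


def row_normalized(confusion: np.ndarray) -> np.ndarray:
    """Row-percentage view of a confusion matrix (rows with no support -> 0)."""
    cm = np.asarray(confusion, dtype=float)
    sums = cm.sum(axis=1, keepdims=True)
    return np.divide(cm, sums, out=np.zeros_like(cm), where=sums > 0) * 100.0


def one_vs_rest_counts(confusion: np.ndarray) -> np.ndarray:
    """Per-class (TP, FP, FN, TN); each row sums to the grand total."""
    cm = np.asarray(confusion)
    total = cm.sum()
    tp = np.diag(cm)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp
    return np.stack([tp, fp, fn, tn], axis=1)


@dataclass
class EvalReport:
    """Confusion matrix plus per-class and macro metrics."""

    confusion: list
    accuracy: float
    accuracy_macro_ovr: float
    recall_per_class: list
    precision_per_class: list
    f_measure_per_class: list
    recall_macro: float
    recall_sd: float
    precision_macro: float
    precision_sd: float
    f_measure_macro: float
    f_measure_sd: float
    class_names: tuple[str, ...] = ACTIVITIES

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    def confusion_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.confusion, index=list(self.class_names),
                     columns=list(self.class_names)).to_csv(path)

    def summary(self) -> str:
        return (f"accuracy {self.accuracy:.4f} | "
                f"recall {self.recall_macro:.4f} ({self.recall_sd:.4f}) | "
                f"precision {self.precision_macro:.4f} ({self.precision_sd:.4f}) | "
                f"F-measure {self.f_measure_macro:.4f} ({self.f_measure_sd:.4f})")


def metrics_from_confusion(confusion: np.ndarray) -> EvalReport:
    """One-vs-rest recall/precision/F per class, macro means with
    across-class SD, and micro accuracy (trace / total)."""
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix must be non-negative")
    total = cm.sum()
    if total == 0:
        raise ValueError("all-zero confusion matrix")
    counts = one_vs_rest_counts(cm)
    tp, fp, fn, tn = counts.T
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(tp + fn > 0, tp / np.where(tp + fn == 0, 1, tp + fn), 0.0)
        precision = np.where(tp + fp > 0, tp / np.where(tp + fp == 0, 1, tp + fp), 0.0)
        denom = precision + recall
        f_measure = np.where(denom > 0, 2 * precision * recall / np.where(denom == 0, 1, denom), 0.0)
    if (tp + fn == 0).any() or (tp + fp == 0).any():
        logger.info("empty class encountered; undefined recall/precision set to 0")
    acc_ovr = (tp + tn) / total
    return EvalReport(
        confusion=cm.astype(int).tolist(),
        accuracy=float(np.trace(cm) / total),
        accuracy_macro_ovr=float(acc_ovr.mean()),
        recall_per_class=recall.tolist(),
        precision_per_class=precision.tolist(),
        f_measure_per_class=f_measure.tolist(),
        recall_macro=float(recall.mean()),
        recall_sd=float(recall.std()),
        precision_macro=float(precision.mean()),
        precision_sd=float(precision.std()),
        f_measure_macro=float(f_measure.mean()),
        f_measure_sd=float(f_measure.std()),
        class_names=tuple(ACTIVITIES[:cm.shape[0]]) if cm.shape[0] <= len(ACTIVITIES)
        else tuple(str(i) for i in range(cm.shape[0])),
    )


def evaluate_model(model: Network, data) -> EvalReport:
    """Predict on a WindowSet (or aligned dict) and report the metrics."""
    x, y = to_arrays(data)
    y_pred = model.predict(x)
    n = max(model.n_classes, int(y.max()) + 1 if y.size else 1)
    return metrics_from_confusion(confusion_matrix(y, y_pred, n_classes=n))
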