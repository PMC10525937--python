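"""Mini-batch training loop: Adam, plateau LR decay, best-weights checkpoint."""

from __future__ import annotations

import numpy as np

from .model import Network, softmax_cross_entropy


class Adam:
    def __init__(self, net: Network, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, name, arr in self.net.parameters():
            g = layer.grads[name]
            key = (id(layer), name)
            m = self._m.setdefault(key, np.zeros_like(arr))
            v = self._v.setdefault(key, np.zeros_like(arr))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class PlateauScheduler:
    """Multiply the LR by ``factor`` after ``patience`` epochs without a
    strictly lower monitored loss; the wait counter resets on improvement
    and after each reduction, so the factor can fire repeatedly."""

    def __init__(self, initial_lr: float, factor: float = 0.9, patience: int = 10):
        if not 0.0 < factor < 1.0:
            raise ValueError("plateau factor must be in (0, 1)")
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.lr = initial_lr
        self.factor = factor
        self.patience = patience
        self.best = np.inf
        self.wait = 0

    def update(self, monitored: float) -> float:
        """Record one epoch's monitored loss; return the LR for the *next* epoch."""
        if monitored < self.best:
            self.best = monitored
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.patience:
                self.lr *= self.factor
                self.wait = 0
        return self.lr


def _take(x, idx):
    if isinstance(x, dict):
        return {k: v[idx] for k, v in x.items()}
    return x[idx]


def _n_samples(x) -> int:
    if isinstance(x, dict):
        return next(iter(x.values())).shape[0]
    return x.shape[0]


def evaluate_loss_acc(net: Network, x, y: np.ndarray, batch_size: int = 256) -> tuple[float, float]:
    n = _n_samples(x)
    total_loss = 0.0
    correct = 0
    for start in range(0, n, batch_size):
        idx = slice(start, min(start + batch_size, n))
        xb, yb = _take(x, idx), y[idx]
        logits = net.forward(xb, training=False)
        loss, _ = softmax_cross_entropy(logits, yb)
        total_loss += loss * len(yb)
        correct += int((logits.argmax(axis=1) == yb).sum())
    return total_loss / n, correct / n


def fit(net: Network, x, y: np.ndarray, *, epochs: int, batch_size: int,
        lr: float, x_val=None, y_val: np.ndarray | None = None,
        plateau_factor: float | None = None, plateau_patience: int = 10,
        checkpoint_best: bool = False, rng: np.random.Generator | None = None,
        shuffle: bool = True, verbose: bool = False) -> dict:
    """Train with Adam and categorical cross-entropy.

    Returns a history dict with per-epoch train/val loss and accuracy and the
    learning-rate trace.  With ``checkpoint_best`` the weights from the epoch
    of minimum validation loss are restored at the end.
    """
    n = _n_samples(x)
    if n == 0:
        raise ValueError("empty training set")
    rng = rng or np.random.default_rng()
    opt = Adam(net, lr)
    sched = PlateauScheduler(lr, plateau_factor, plateau_patience) if plateau_factor else None
    history: dict[str, list] = {"loss": [], "acc": [], "val_loss": [], "val_acc": [], "lr": []}
    best_val = np.inf
    best_weights = None
    best_epoch = -1
    for epoch in range(epochs):
        order = rng.permutation(n) if shuffle else np.arange(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = _take(x, idx), y[idx]
            logits = net.forward(xb, training=True)
            loss, grad = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            net.backward(grad)
            opt.step()
            epoch_loss += loss * len(yb)
            correct += int((logits.argmax(axis=1) == yb).sum())
        history["loss"].append(epoch_loss / n)
        history["acc"].append(correct / n)
        history["lr"].append(opt.lr)
        if x_val is not None and y_val is not None:
            vl, va = evaluate_loss_acc(net, x_val, y_val, batch_size=max(batch_size, 256))
            history["val_loss"].append(vl)
            history["val_acc"].append(va)
            if checkpoint_best and vl < best_val:
                best_val = vl
                best_weights = net.get_weights()
                best_epoch = epoch
            if sched is not None:
                opt.lr = sched.update(vl)
        if verbose:
            msg = f"epoch {epoch + 1}/{epochs} loss={history['loss'][-1]:.4f}"
            if history["val_loss"]:
                msg += f" val_loss={history['val_loss'][-1]:.4f} val_acc={history['val_acc'][-1]:.4f}"
            print(msg)
    if checkpoint_best and best_weights is not None:
        net.set_weights(best_weights)
        history["checkpoint_epoch"] = best_epoch
    return history
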