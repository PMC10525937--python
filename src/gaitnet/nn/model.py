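"""Network container: one layer stack per input head, a shared trunk, softmax out.

A single-input network is the degenerate case of one head.  Heads end in a
``Flatten``; the trunk consumes the concatenation of the flattened head
outputs.  The final trunk layer produces class logits; probabilities come
from a softmax applied at prediction / loss time (the softmax itself has no
parameters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Layer


@dataclass(frozen=True)
class ParamCount:
    trainable: int
    non_trainable: int

    @property
    def total(self) -> int:
        return self.trainable + self.non_trainable


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean CE loss over integer labels and the gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Network:
    """Multi-head feed-forward network over ``(batch, time, channels)`` inputs."""

    def __init__(self, heads: list[tuple[str, list[Layer]]], trunk: list[Layer],
                 n_classes: int):
        if not heads:
            raise ValueError("network needs at least one head")
        self.heads = heads
        self.trunk = trunk
        self.n_classes = n_classes
        self._head_widths: list[int] | None = None

    # -- plumbing ---------------------------------------------------------
    @property
    def head_names(self) -> list[str]:
        return [name for name, _ in self.heads]

    def _as_inputs(self, x) -> list[np.ndarray]:
        if isinstance(x, dict):
            return [x[name] for name in self.head_names]
        if len(self.heads) != 1:
            raise ValueError("multi-head network needs a dict of inputs")
        return [x]

    def layers(self):
        for _, stack in self.heads:
            yield from stack
        yield from self.trunk

    def parameters(self):
        """Yield (layer, name, array) for every trainable parameter."""
        for layer in self.layers():
            for name, arr in layer.params.items():
                yield layer, name, arr

    def param_count(self) -> ParamCount:
        trainable = sum(layer.n_trainable for layer in self.layers())
        non_trainable = sum(layer.n_non_trainable for layer in self.layers())
        return ParamCount(trainable, non_trainable)

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers():
            out.extend(arr.copy() for arr in layer.params.values())
            out.extend(arr.copy() for arr in layer.stats.values())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers():
            for name in layer.params:
                layer.params[name] = next(it).copy()
            for name in layer.stats:
                layer.stats[name] = next(it).copy()

    # -- forward / backward ----------------------------------------------
    def forward(self, x, training: bool = False) -> np.ndarray:
        inputs = self._as_inputs(x)
        feats = []
        for (name, stack), xi in zip(self.heads, inputs):
            h = xi
            for layer in stack:
                h = layer.forward(h, training=training)
            feats.append(h)
        self._head_widths = [f.shape[1] for f in feats]
        h = feats[0] if len(feats) == 1 else np.concatenate(feats, axis=1)
        for layer in self.trunk:
            h = layer.forward(h, training=training)
        return h

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.trunk):
            grad = layer.backward(grad)
        offsets = np.cumsum([0] + self._head_widths)
        for k in reversed(range(len(self.heads))):
            g = grad[:, offsets[k]:offsets[k + 1]]
            for layer in reversed(self.heads[k][1]):
                g = layer.backward(g)

    def predict_proba(self, x, batch_size: int = 256) -> np.ndarray:
        inputs = self._as_inputs(x)
        n = inputs[0].shape[0]
        out = np.empty((n, self.n_classes))
        for start in range(0, n, batch_size):
            sl = slice(start, min(start + batch_size, n))
            xb = {name: xi[sl] for (name, _), xi in zip(self.heads, inputs)}
            if len(self.heads) == 1:
                xb = xb[self.head_names[0]]
            out[sl] = softmax(self.forward(xb, training=False))
        return out

    def predict(self, x, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(x, batch_size=batch_size).argmax(axis=1)
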