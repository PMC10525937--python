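"""Minimal 1-D neural-network layers with hand-derived backprop.

Every layer follows the same contract: ``forward(x, training)`` caches what
backprop needs, ``backward(grad)`` fills ``self.grads`` (same keys as
``self.params``) and returns the gradient with respect to the input.
Sequence tensors are ``(batch, time, channels)``; dense tensors are
``(batch, features)``.  Only the operations the architecture family and the
benchmark networks need are implemented: stride-1 convolutions, pool size 2,
and so on.  Trainable parameters live in ``params``; running statistics
(batch-norm moving moments) live in ``stats`` and are counted as
non-trainable.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base layer: parameter-free identity."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.stats: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_trainable(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    @property
    def n_non_trainable(self) -> int:
        return int(sum(s.size for s in self.stats.values()))

    def output_shape(self, input_shape: tuple) -> tuple:
        """Shape excluding the batch axis."""
        return input_shape


class Conv1D(Layer):
    """Temporal convolution, stride 1, padding 'same' or 'valid'.

    Weight shape ``(kernel, in_channels, filters)``; parameter count is the
    conv1d closed form k*c_in*f + f.
    """

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 padding: str = "same", rng: np.random.Generator | None = None):
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        rng = rng or np.random.default_rng()
        self.kernel_size = int(kernel_size)
        self.in_channels = int(in_channels)
        self.filters = int(filters)
        self.padding = padding
        fan_in = self.kernel_size * self.in_channels
        scale = np.sqrt(2.0 / fan_in)  # He init, layers are ReLU-followed
        self.params = {
            "W": rng.normal(0.0, scale, size=(self.kernel_size, self.in_channels, self.filters)),
            "b": np.zeros(self.filters),
        }

    def _pad(self) -> tuple[int, int]:
        if self.padding == "valid":
            return 0, 0
        total = self.kernel_size - 1
        return total // 2, total - total // 2

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k = self.kernel_size
        pl, pr = self._pad()
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0))) if (pl or pr) else x
        n, tp, c = xp.shape
        t_out = tp - k + 1
        if t_out < 1:
            raise ValueError("input shorter than kernel")
        # (n, t_out, c, k) -> (n, t_out, k*c) with kernel-major ordering
        cols = sliding_window_view(xp, k, axis=1).transpose(0, 1, 3, 2)
        cols = np.ascontiguousarray(cols).reshape(n, t_out, k * c)
        self._cache = (xp.shape, cols, x.shape)
        wmat = self.params["W"].reshape(k * c, self.filters)
        return cols @ wmat + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp_shape, cols, x_shape = self._cache
        k, c, f = self.kernel_size, self.in_channels, self.filters
        n, t_out, _ = grad.shape
        gm = grad.reshape(-1, f)
        self.grads["W"] = (cols.reshape(-1, k * c).T @ gm).reshape(k, c, f)
        self.grads["b"] = gm.sum(axis=0)
        dcols = (grad @ self.params["W"].reshape(k * c, f).T).reshape(n, t_out, k, c)
        dxp = np.zeros(xp_shape)
        for i in range(k):
            dxp[:, i:i + t_out, :] += dcols[:, :, i, :]
        pl, _ = self._pad()
        return dxp[:, pl:pl + x_shape[1], :]

    def output_shape(self, input_shape: tuple) -> tuple:
        t, _ = input_shape
        t_out = t if self.padding == "same" else t - self.kernel_size + 1
        if t_out < 1:
            raise ValueError("temporal axis collapsed in Conv1D")
        return (t_out, self.filters)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        limit = np.sqrt(6.0 / (in_features + out_features))  # Glorot uniform
        self.params = {
            "W": rng.uniform(-limit, limit, size=(in_features, out_features)),
            "b": np.zeros(out_features),
        }

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T

    def output_shape(self, input_shape: tuple) -> tuple:
        return (self.params["W"].shape[1],)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class BatchNorm(Layer):
    """Batch normalization over the trailing (channel) axis.

    2*channels trainable (gamma, beta) and 2*channels non-trainable
    (moving mean/variance) parameters, the standard accounting.
    """

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.stats = {"moving_mean": np.zeros(channels), "moving_var": np.ones(channels)}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.stats["moving_mean"] = m * self.stats["moving_mean"] + (1 - m) * mean
            self.stats["moving_var"] = m * self.stats["moving_var"] + (1 - m) * var
        else:
            mean = self.stats["moving_mean"]
            var = self.stats["moving_var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, x.shape)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, axes, shape = self._cache
        m = int(np.prod([shape[a] for a in axes]))
        self.grads["gamma"] = (grad * xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        g = grad * self.params["gamma"]
        # batch-statistics backprop (training mode)
        dx = (g - g.mean(axis=axes) - xhat * (g * xhat).mean(axis=axes)) * inv
        return dx


class _Pool1D(Layer):
    """Pool size 2, valid padding: a trailing odd timestep is dropped."""

    pool = 2

    def output_shape(self, input_shape: tuple) -> tuple:
        t, c = input_shape
        t_out = t // self.pool
        if t_out < 1:
            raise ValueError("temporal axis collapsed in pooling")
        return (t_out, c)


class MaxPool1D(_Pool1D):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, t, c = x.shape
        t2 = t // 2
        xr = x[:, :t2 * 2, :].reshape(n, t2, 2, c)
        self._idx = xr.argmax(axis=2)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, t, c = self._in_shape
        t2 = t // 2
        dxr = np.zeros((n, t2, 2, c))
        np.put_along_axis(dxr, self._idx[:, :, None, :], grad[:, :, None, :], axis=2)
        dx = np.zeros(self._in_shape)
        dx[:, :t2 * 2, :] = dxr.reshape(n, t2 * 2, c)
        return dx


class AvgPool1D(_Pool1D):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, t, c = x.shape
        t2 = t // 2
        self._in_shape = x.shape
        return x[:, :t2 * 2, :].reshape(n, t2, 2, c).mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, t, c = self._in_shape
        t2 = t // 2
        dx = np.zeros(self._in_shape)
        dx[:, :t2 * 2, :] = np.repeat(grad / 2.0, 2, axis=1)
        return dx


class GlobalAvgPool1D(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._t = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, None, :], self._t, axis=1) / self._t

    def output_shape(self, input_shape: tuple) -> tuple:
        return (input_shape[1],)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)

    def output_shape(self, input_shape: tuple) -> tuple:
        return (int(np.prod(input_shape)),)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = self.rng.random(x.shape) < keep
        return x * self._mask / keep

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask / (1.0 - self.rate)


class LSTM(Layer):
    """Single LSTM layer, tanh cell / sigmoid gates, gate order (i, f, g, o).

    Parameter count follows the closed form 4*((d + u)*u + u) for input
    dimension d and u units.  Forget-gate bias is initialized to 1.
    """

    def __init__(self, in_features: int, units: int, return_sequences: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        d, u = int(in_features), int(units)
        self.units = u
        self.return_sequences = return_sequences
        lim_w = np.sqrt(6.0 / (d + 4 * u))
        lim_u = np.sqrt(6.0 / (u + 4 * u))
        b = np.zeros(4 * u)
        b[u:2 * u] = 1.0
        self.params = {
            "W": rng.uniform(-lim_w, lim_w, size=(d, 4 * u)),
            "U": rng.uniform(-lim_u, lim_u, size=(u, 4 * u)),
            "b": b,
        }

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, t, d = x.shape
        u = self.units
        h = np.zeros((n, u))
        c = np.zeros((n, u))
        hs = np.empty((n, t, u))
        self._cache = []
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        for step in range(t):
            x_t = x[:, step, :]
            z = x_t @ W + h @ U + b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = _sigmoid(z[:, 3 * u:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, step, :] = h
            self._cache.append((x_t, h_prev, c_prev, i, f, g, o, tc))
        self._x_shape = x.shape
        return hs if self.return_sequences else h

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, t, d = self._x_shape
        u = self.units
        W, U = self.params["W"], self.params["U"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params["b"])
        dx = np.empty((n, t, d))
        dh_next = np.zeros((n, u))
        dc_next = np.zeros((n, u))
        for step in reversed(range(t)):
            x_t, h_prev, c_prev, i, f, g, o, tc = self._cache[step]
            if self.return_sequences:
                dh = grad[:, step, :] + dh_next
            else:
                dh = (grad if step == t - 1 else 0.0) + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g * g),
                do * o * (1 - o),
            ], axis=1)
            dW += x_t.T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, step, :] = dz @ W.T
            dh_next = dz @ U.T
            dc_next = dc * f
        self.grads = {"W": dW, "U": dU, "b": db}
        return dx

    def output_shape(self, input_shape: tuple) -> tuple:
        t, _ = input_shape
        return (t, self.units) if self.return_sequences else (self.units,)
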