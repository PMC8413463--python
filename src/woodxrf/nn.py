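"""Minimal 1D convolutional network engine in numpy.

Implements exactly the layer zoo the spectral classifier needs — valid-padding
1D convolution, batch normalization, ReLU, max pooling, dense layers with
inverted dropout, and a softmax/categorical-crossentropy head — together with
the Nadam optimizer.  Everything runs in float32 on the CPU; convolutions are
lowered to BLAS matrix products via sliding-window views, which keeps a
full training run of the spectral classifier within minutes on one core.

The engine is deliberately small and fully deterministic: all stochastic
choices (weight init, shuffling, dropout masks) come from explicit
``numpy.random.Generator`` instances, so a fixed seed reproduces a training
run bit for bit.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

try:  # single fused pass over the parameter vector; pure-numpy fallback below
    from numba import njit as _njit

    @_njit("void(float32[::1], float32[::1], float32[::1], float32[::1], "
           "float32, float32, float32, float32, float32, float32)",
           cache=True, fastmath=True)
    def _nadam_kernel(p, g, m, v, lr, b1, b2, eps, bc1, bc2):  # pragma: no cover
        c1 = np.float32(1.0) - b1
        c2 = np.float32(1.0) - b2
        a_m = lr * b1 / bc1  # lr * (b1 * mhat) term
        a_g = lr * c1 / bc1  # lr * ((1-b1) * ghat) term
        s_v = np.float32(1.0) / np.sqrt(bc2)
        tiny = np.float32(1e-30)  # flush to zero before the subnormal band:
        for i in range(p.size):   # denormal arithmetic is ~10x slower on x86
            gi = g[i]
            mi = b1 * m[i] + c1 * gi
            vi = b2 * v[i] + c2 * gi * gi
            if -tiny < mi < tiny:
                mi = np.float32(0.0)
            if vi < tiny:
                vi = np.float32(0.0)
            m[i] = mi
            v[i] = vi
            p[i] -= (a_m * mi + a_g * gi) / (np.sqrt(vi) * s_v + eps)

except ImportError:  # pragma: no cover
    _nadam_kernel = None

__all__ = [
    "Conv1D",
    "BatchNorm",
    "ReLU",
    "MaxPool1D",
    "Flatten",
    "Dense",
    "Dropout",
    "Network",
    "Nadam",
    "softmax",
    "softmax_crossentropy",
]

_DT = np.float32


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilised."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_crossentropy(logits: np.ndarray, onehot: np.ndarray):
    """Mean categorical crossentropy and the gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(_DT).tiny
    loss = float(-(onehot * np.log(np.maximum(p, eps))).sum() / n)
    grad = (p - onehot) / n
    return loss, grad.astype(_DT, copy=False)


class Layer:
    """Base layer: forward/backward plus a list of (param, grad) slots."""

    trainable: bool = True

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None):
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[dict]:
        return []

    def out_shape(self, in_shape: tuple) -> tuple:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid-padding, stride-1 cross-correlation along the energy axis.

    Input ``(n, length, c_in)`` -> output ``(n, length - kernel + 1, filters)``.
    Weights use Glorot-uniform initialisation, the convention of the
    mainstream deep-learning frameworks this architecture follows.
    """

    def __init__(self, c_in: int, filters: int, kernel: int, rng: np.random.Generator):
        self.c_in, self.filters, self.kernel = c_in, filters, kernel
        fan_in = kernel * c_in
        limit = np.sqrt(6.0 / (fan_in + filters))
        self.w = rng.uniform(-limit, limit, (fan_in, filters)).astype(_DT, copy=False)
        self.b = np.zeros(filters, dtype=_DT)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def out_shape(self, in_shape):
        n, length, _ = in_shape
        if length < self.kernel:
            raise ValueError(f"conv kernel {self.kernel} exceeds input length {length}")
        return (n, length - self.kernel + 1, self.filters)

    def forward(self, x, training, rng):
        # (n, L, c) -> patches (n, L_out, kernel, c) -> flat (n, L_out, kernel*c)
        n, length, c = x.shape
        lo = length - self.kernel + 1
        patches = sliding_window_view(x, self.kernel, axis=1)  # (n, lo, c, k)
        patches = np.ascontiguousarray(patches.transpose(0, 1, 3, 2)).reshape(n, lo, -1)
        self._patches = patches
        self._in_shape = x.shape
        return patches @ self.w + self.b

    def backward(self, dy):
        n, lo, _ = dy.shape
        flat_p = self._patches.reshape(-1, self.kernel * self.c_in)
        flat_d = dy.reshape(-1, self.filters)
        self.dw = (flat_p.T @ flat_d).astype(_DT, copy=False)
        self.db = flat_d.sum(axis=0).astype(_DT, copy=False)
        dpatch = (dy @ self.w.T).reshape(n, lo, self.kernel, self.c_in)
        dx = np.zeros(self._in_shape, dtype=_DT)
        for k in range(self.kernel):  # fold overlapping patch gradients back
            dx[:, k : k + lo, :] += dpatch[:, :, k, :]
        return dx

    def params(self):
        return [
            {"layer": self, "name": "w"},
            {"layer": self, "name": "b"},
        ]


class BatchNorm(Layer):
    """Per-channel batch normalization (statistics over batch and position).

    Batch statistics in training, exponential running averages at inference;
    momentum 0.99 and epsilon 1e-3.
    """

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = np.ones(channels, dtype=_DT)
        self.beta = np.zeros(channels, dtype=_DT)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=_DT)
        self.running_var = np.ones(channels, dtype=_DT)
        self.momentum = momentum
        self.eps = eps

    def out_shape(self, in_shape):
        return in_shape

    def _axes(self, x):
        return tuple(range(x.ndim - 1))

    def forward(self, x, training, rng):
        axes = self._axes(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(_DT, copy=False)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(_DT, copy=False)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._xhat, self._inv, self._nred = xhat, inv, int(np.prod([x.shape[a] for a in axes]))
        return (self.gamma * xhat + self.beta).astype(_DT, copy=False)

    def backward(self, dy):
        axes = self._axes(dy)
        xhat, inv, nred = self._xhat, self._inv, self._nred
        self.dgamma = (dy * xhat).sum(axis=axes).astype(_DT, copy=False)
        self.dbeta = dy.sum(axis=axes).astype(_DT, copy=False)
        dxhat = dy * self.gamma
        dx = (inv / nred) * (
            nred * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
        )
        return dx.astype(_DT, copy=False)

    def params(self):
        return [
            {"layer": self, "name": "gamma"},
            {"layer": self, "name": "beta"},
        ]


class ReLU(Layer):
    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, training, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class MaxPool1D(Layer):
    """Non-overlapping max pooling (size == stride); trailing odd element dropped."""

    def __init__(self, size: int = 2):
        self.size = size

    def out_shape(self, in_shape):
        n, length, c = in_shape
        if length < self.size:
            raise ValueError(f"pool size {self.size} exceeds input length {length}")
        return (n, length // self.size, c)

    def forward(self, x, training, rng):
        n, length, c = x.shape
        lo = length // self.size
        xt = x[:, : lo * self.size, :].reshape(n, lo, self.size, c)
        self._arg = xt.argmax(axis=2)  # first occurrence on ties
        self._in_shape = x.shape
        return np.take_along_axis(xt, self._arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        n, length, c = self._in_shape
        lo = length // self.size
        dxt = np.zeros((n, lo, self.size, c), dtype=_DT)
        np.put_along_axis(dxt, self._arg[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(self._in_shape, dtype=_DT)
        dx[:, : lo * self.size, :] = dxt.reshape(n, lo * self.size, c)
        return dx


class Flatten(Layer):
    def out_shape(self, in_shape):
        n = in_shape[0]
        return (n, int(np.prod(in_shape[1:])))

    def forward(self, x, training, rng):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Dense(Layer):
    """Fully connected layer with Glorot-uniform initial weights."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, (n_in, n_out)).astype(_DT, copy=False)
        self.b = np.zeros(n_out, dtype=_DT)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def out_shape(self, in_shape):
        return (in_shape[0], self.w.shape[1])

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw = (self._x.T @ dy).astype(_DT, copy=False)
        self.db = dy.sum(axis=0).astype(_DT, copy=False)
        return dy @ self.w.T

    def params(self):
        return [
            {"layer": self, "name": "w"},
            {"layer": self, "name": "b"},
        ]


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, training, rng):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(_DT, copy=False) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Network:
    """A plain sequential stack ending in logits (softmax applied by the loss)."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        h = np.asarray(x, dtype=_DT)
        for layer in self.layers:
            h = layer.forward(h, training, rng)
        return h

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def params(self) -> list[dict]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(getattr(p["layer"], p["name"]).size for p in self.params()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All trainable and running-statistic arrays, keyed for persistence."""
        out = {}
        for i, layer in enumerate(self.layers):
            for name in ("w", "b", "gamma", "beta", "running_mean", "running_var"):
                if hasattr(layer, name):
                    out[f"layer{i:02d}.{name}"] = getattr(layer, name)
        return out

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        expected = self.state_arrays()
        if set(arrays) != set(expected):
            missing = set(expected) ^ set(arrays)
            raise KeyError(f"state mismatch for keys: {sorted(missing)}")
        for i, layer in enumerate(self.layers):
            for name in ("w", "b", "gamma", "beta", "running_mean", "running_var"):
                key = f"layer{i:02d}.{name}"
                if key in arrays:
                    current = getattr(layer, name)
                    incoming = np.asarray(arrays[key], dtype=current.dtype)
                    if incoming.shape != current.shape:
                        raise ValueError(f"shape mismatch for {key}")
                    setattr(layer, name, incoming.copy())


class Nadam:
    """Nesterov-accelerated Adam (Dozat 2016), the Keras-default constants.

    update_t = lr * (beta1*mhat + (1-beta1)*g/(1-beta1^t)) / (sqrt(vhat)+eps)
    """

    def __init__(self, lr: float = 1e-5, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, params: list[dict]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, slot in enumerate(params):
            layer, name = slot["layer"], slot["name"]
            g = getattr(layer, "d" + name)
            m = self._m.get(i)
            if m is None:
                m = self._m[i] = np.zeros_like(g)
                self._v[i] = np.zeros_like(g)
            v = self._v[i]
            arr = getattr(layer, name)
            if (_nadam_kernel is not None and arr.dtype == np.float32
                    and arr.flags.c_contiguous and g.flags.c_contiguous):
                _nadam_kernel(arr.ravel(), g.ravel(), m.ravel(), v.ravel(),
                              np.float32(self.lr), np.float32(b1), np.float32(b2),
                              np.float32(self.eps), np.float32(bc1), np.float32(bc2))
                continue
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            np.copyto(m, 0, where=np.abs(m) < 1e-30)  # keep out of denormals
            np.copyto(v, 0, where=v < 1e-30)
            mhat = m / bc1
            vhat = v / bc2
            update = self.lr * (b1 * mhat + (1 - b1) * g / bc1) / (np.sqrt(vhat) + self.eps)
            arr -= update.astype(arr.dtype)
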