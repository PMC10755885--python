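"""A compact numpy backend for block-structured 1D convolutional networks.

Implements exactly the layer set the seizure-detection architecture needs —
same-padded Conv1D with a fused activation, batch normalization, inverted
dropout, ceil-mode max pooling, flatten, and a softmax dense head — together
with reverse-mode gradients and an Adam optimizer.  Convolution is expressed
as a sliding-window im2col followed by one matrix multiply, so the heavy
lifting happens inside BLAS.

All arithmetic is float32.  Weight initialization and dropout masks are
driven by explicit ``numpy.random.Generator`` objects, which makes training
runs bit-reproducible on a fixed seed.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv1D",
    "BatchNorm1D",
    "Dropout",
    "MaxPool1D",
    "Flatten",
    "DenseSoftmax",
    "Network",
    "Adam",
    "softmax",
]

_DT = np.float32


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _activate(name: str, x: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "sigmoid":
        # clamp to keep float32 exp finite
        return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
    if name == "tanh":
        return np.tanh(x)
    if name == "linear":
        return x
    raise ValueError(f"unknown activation {name!r}")


def _activate_grad(name: str, y: np.ndarray, dy: np.ndarray) -> np.ndarray:
    # derivative expressed through the activation output y
    if name == "relu":
        return dy * (y > 0.0)
    if name == "sigmoid":
        return dy * y * (1.0 - y)
    if name == "tanh":
        return dy * (1.0 - y * y)
    if name == "linear":
        return dy
    raise ValueError(f"unknown activation {name!r}")


class Layer:
    """Minimal layer protocol: forward/backward plus parameter access."""

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv1D(Layer):
    """Stride-1, length-preserving ('same') 1D convolution with activation."""

    def __init__(
        self,
        in_channels: int,
        filters: int,
        kernel_size: int,
        activation: str = "relu",
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        self.k = kernel_size
        self.cin = in_channels
        self.cout = filters
        self.activation = activation
        limit = math.sqrt(6.0 / (kernel_size * in_channels + kernel_size * filters))
        self.W = rng.uniform(-limit, limit, size=(kernel_size * in_channels, filters)).astype(_DT)
        self.b = np.zeros(filters, dtype=_DT)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._pad_left = (kernel_size - 1) // 2
        self._pad_right = kernel_size - 1 - self._pad_left

    def forward(self, x, training, rng):
        B, L, _ = x.shape
        xp = np.pad(x, ((0, 0), (self._pad_left, self._pad_right), (0, 0)))
        # (B, L, Cin, k) -> (B, L, k, Cin) -> (B*L, k*Cin)
        cols = sliding_window_view(xp, self.k, axis=1)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(B * L, self.k * self.cin)
        y = (cols @ self.W + self.b).reshape(B, L, self.cout)
        y = _activate(self.activation, y)
        if training:
            self._cols = cols
            self._out = y
            self._in_len = L
        return y

    def backward(self, dy):
        B, L, _ = dy.shape
        dz = _activate_grad(self.activation, self._out, dy).reshape(B * L, self.cout)
        self.dW[...] = self._cols.T @ dz
        self.db[...] = dz.sum(axis=0)
        dcols = (dz @ self.W.T).reshape(B, L, self.k, self.cin)
        dxp = np.zeros((B, L + self.k - 1, self.cin), dtype=_DT)
        for j in range(self.k):
            dxp[:, j : j + L, :] += dcols[:, :, j, :]
        self._cols = self._out = None
        return dxp[:, self._pad_left : self._pad_left + L, :]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class BatchNorm1D(Layer):
    """Per-channel batch normalization over the (batch, length) axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=_DT)
        self.beta = np.zeros(channels, dtype=_DT)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=_DT)
        self.running_var = np.ones(channels, dtype=_DT)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training, rng):
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_std
            self._xhat = xhat.astype(_DT)
            self._inv_std = inv_std.astype(_DT)
            self._n = x.shape[0] * x.shape[1]
            return (self.gamma * self._xhat + self.beta).astype(_DT)
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        return (self.gamma * (x - self.running_mean) * inv_std + self.beta).astype(_DT)

    def backward(self, dy):
        xhat, inv_std, n = self._xhat, self._inv_std, self._n
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 1))
        self.dbeta[...] = dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 1))
            - xhat * (dxhat * xhat).sum(axis=(0, 1)) / n
        ) * inv_std
        self._xhat = None
        return dx.astype(_DT)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class Dropout(Layer):
    """Inverted dropout: active only during training."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(_DT) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class MaxPool1D(Layer):
    """Ceil-mode max pooling: output length = ceil(L / pool)."""

    def __init__(self, pool: int):
        if pool < 1:
            raise ValueError("pool size must be >= 1")
        self.pool = pool

    def forward(self, x, training, rng):
        B, L, C = x.shape
        m = self.pool
        out_len = -(-L // m)  # ceil
        pad = out_len * m - L
        if pad:
            xp = np.pad(x, ((0, 0), (0, pad), (0, 0)), constant_values=-np.inf)
        else:
            xp = x
        xr = xp.reshape(B, out_len, m, C)
        idx = xr.argmax(axis=2)
        y = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
        if training:
            self._idx = idx
            self._in_len = L
            self._shape = (B, out_len, m, C)
        return y

    def backward(self, dy):
        B, out_len, m, C = self._shape
        dxr = np.zeros(self._shape, dtype=_DT)
        np.put_along_axis(dxr, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = dxr.reshape(B, out_len * m, C)[:, : self._in_len, :]
        self._idx = None
        return dx


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class DenseSoftmax(Layer):
    """Fully connected classifier head with a softmax output.

    ``backward`` expects the gradient with respect to the logits (for
    cross-entropy that is ``(probs - onehot) / batch``), which avoids the
    numerically awkward Jacobian of softmax itself.
    """

    def __init__(self, in_features: int, units: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        limit = math.sqrt(6.0 / (in_features + units))
        self.W = rng.uniform(-limit, limit, size=(in_features, units)).astype(_DT)
        self.b = np.zeros(units, dtype=_DT)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training, rng):
        if training:
            self._in = x
        return softmax(x @ self.W + self.b)

    def backward(self, dlogits):
        self.dW[...] = self._in.T @ dlogits
        self.db[...] = dlogits.sum(axis=0)
        dx = dlogits @ self.W.T
        self._in = None
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Network:
    """An ordered layer stack behaving as a probabilistic classifier."""

    def __init__(self, layers: Sequence[Layer], seed: int = 0):
        self.layers = list(layers)
        self.rng = np.random.default_rng(seed)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(x, dtype=_DT), training=False)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = np.asarray(x, dtype=_DT)
        for layer in self.layers:
            out = layer.forward(out, training, self.rng)
        return out

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        grad = dlogits.astype(_DT)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def output_shapes(self, input_shape: tuple[int, int], batch_size: int = 2) -> list[tuple]:
        """Per-layer output shapes observed on a dummy forward pass."""
        x = np.zeros((batch_size, *input_shape), dtype=_DT)
        shapes = []
        for layer in self.layers:
            x = layer.forward(x, False, self.rng)
            shapes.append(x.shape[1:])
        return shapes

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def get_weights(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm1D):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_weights(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        for p, s in zip(params, state[: len(params)]):
            p[...] = s
        extra = iter(state[len(params) :])
        for layer in self.layers:
            if isinstance(layer, BatchNorm1D):
                layer.running_mean[...] = next(extra)
                layer.running_var[...] = next(extra)


class Adam:
    """Adam with the standard bias-corrected first/second moment estimates."""

    def __init__(
        self,
        params: Sequence[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
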