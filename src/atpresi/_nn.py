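"""Minimal NumPy building blocks for the 1-D convolutional classifier.

Layers operate on arrays of shape (batch, width, channels); each exposes
``forward(x, training)`` and ``backward(grad)`` and registers its
parameters with the shared Adam optimiser.  Only what the ATP-binding
classifier needs is implemented: same-padded 1-D convolution, batch
normalisation, ReLU, inverted dropout, flatten and dense layers, with a
sigmoid/binary-cross-entropy head handled by the training loop.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Same-padded 1-D convolution, stride 1, He-initialised."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator):
        self.k = kernel_size
        self.c_in = c_in
        fan_in = c_in * kernel_size
        self.W = Param((rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(np.float32))
        self.b = Param(np.zeros(c_out, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        n, w, _ = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        # (n, w, c_in, k) -> (n, w, c_in * k), matching W's (c_in, k) layout
        cols = sliding_window_view(xp, self.k, axis=1)
        self._cols = cols.reshape(n, w, -1)
        self._in_shape = x.shape
        return self._cols @ self.W.value + self.b.value

    def backward(self, grad):
        n, w, c_out = grad.shape
        flat_cols = self._cols.reshape(-1, self._cols.shape[-1])
        flat_grad = grad.reshape(-1, c_out)
        self.W.grad = flat_cols.T @ flat_grad
        self.b.grad = flat_grad.sum(axis=0)
        dcols = (grad @ self.W.value.T).reshape(n, w, self.c_in, self.k)
        pad = self.k // 2
        dxp = np.zeros((n, w + 2 * pad, self.c_in), dtype=grad.dtype)
        for k in range(self.k):
            dxp[:, k : k + w, :] += dcols[:, :, :, k]
        return dxp[:, pad : pad + w, :]


class BatchNorm(Layer):
    """Per-channel batch normalisation over (batch, width)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training):
        n = x.shape[0] * x.shape[1]
        flat = x.reshape(n, x.shape[2])
        if training:
            mean = flat.mean(axis=0)
            var = np.einsum("ij,ij->j", flat, flat) / n - mean * mean
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._n = n
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        n = self._n
        gflat = grad.reshape(n, grad.shape[2])
        xhat_flat = self._xhat.reshape(n, grad.shape[2])
        self.gamma.grad = np.einsum("ij,ij->j", gflat, xhat_flat)
        self.beta.grad = gflat.sum(axis=0)
        coef = self.gamma.value / self._std
        return (
            grad - self.beta.grad / n - self._xhat * (self.gamma.grad / n)
        ) * coef


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape, dtype=np.float32) < keep) / np.float32(keep)).astype(np.float32)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Param((rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)).astype(np.float32))
        self.b = Param(np.zeros(d_out, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad = self._x.T @ grad
        self.b.grad = grad.sum(axis=0)
        return grad @ self.W.value.T


class Network:
    """A feed-forward stack with a sigmoid/binary-cross-entropy head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return expit(x[:, 0])

    def backward(self, probs: np.ndarray, y: np.ndarray) -> None:
        # d(BCE)/d(logit) = p - y, averaged over the batch
        grad = ((probs - y) / len(y)).astype(np.float32)[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p.value = w.copy()

    def bn_state(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [
            (l.running_mean.copy(), l.running_var.copy())
            for l in self.layers
            if isinstance(l, BatchNorm)
        ]

    def set_bn_state(self, state) -> None:
        bns = [l for l in self.layers if isinstance(l, BatchNorm)]
        for l, (mean, var) in zip(bns, state):
            l.running_mean, l.running_var = mean.copy(), var.copy()


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad**2
            m_hat = p.m / (1 - b1**self.t)
            v_hat = p.v / (1 - b2**self.t)
            p.value = p.value - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def bce_loss(probs: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    p = np.clip(probs.astype(np.float64), eps, 1 - eps)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())
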