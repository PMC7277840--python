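"""Minimal CNN engine in NumPy.

Implements exactly the pieces the view classifier and the LVEF regressor
need: 3x3 same-padded convolutions, ReLU, 2x2 max-pooling, dense layers,
softmax cross-entropy and mean-squared-error losses, and the Adam
optimizer with its standard defaults (lr 1e-3, beta1 0.9, beta2 0.999,
eps 1e-8).  Forward and backward passes are vectorized over mini-batches
and gradients are exact (verified against finite differences in the test
suite).  All arithmetic is float32.

Layout convention: images travel through the network channels-last,
``(N, H, W, C)`` — convolutions then reduce to one matrix product per
kernel offset on nearly-contiguous slices, which is what keeps a pure
NumPy implementation fast enough for desk-scale training.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D", "ReLU", "MaxPool2", "Flatten", "Dense",
    "Sequential", "Adam",
    "softmax", "cross_entropy", "mse",
]

DTYPE = np.float32


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)


def mse(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and gradient for a scalar regression head."""
    pred = pred.reshape(-1)
    diff = pred - target
    loss = float(np.mean(diff ** 2))
    grad = (2.0 * diff / len(diff)).astype(DTYPE).reshape(-1, 1)
    return loss, grad


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """k x k convolution, stride 1, zero same-padding, He-initialized.

    The kernel is stored as ``(k, k, in_ch, out_ch)``; forward computes
    one ``(N*H*W, in_ch) @ (in_ch, out_ch)`` product per kernel offset
    and accumulates.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, k: int = 3):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        fan_in = in_ch * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k * k * in_ch, out_ch))
        self.params = [w.astype(DTYPE), np.zeros(out_ch, dtype=DTYPE)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))).astype(DTYPE, copy=False)
        cols = np.empty((n, h, w, k * k * c), dtype=DTYPE)
        for i, (di, dj) in enumerate((a, b) for a in range(k) for b in range(k)):
            cols[..., i * c:(i + 1) * c] = xp[:, di:di + h, dj:dj + w, :]
        self._cols, self._xshape = cols.reshape(n * h * w, k * k * c), x.shape
        out = self._cols @ self.params[0] + self.params[1]
        return out.reshape(n, h, w, self.out_ch)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        k, p = self.k, self.k // 2
        g = np.ascontiguousarray(gy, dtype=DTYPE).reshape(n * h * w, self.out_ch)
        self.grads[0][...] = self._cols.T @ g
        self.grads[1][...] = g.sum(axis=0)
        dcols = (g @ self.params[0].T).reshape(n, h, w, k * k * c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=DTYPE)
        for i, (di, dj) in enumerate((a, b) for a in range(k) for b in range(k)):
            dxp[:, di:di + h, dj:dj + w, :] += dcols[..., i * c:(i + 1) * c]
        return dxp[:, p:p + h, p:p + w, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(DTYPE)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0).astype(DTYPE)


class LeakyReLU(Layer):
    """max(x, alpha*x); keeps a small gradient where ReLU would die.

    Used in the small regression heads, which can otherwise collapse to
    a constant (all units dead) on unlucky initializations.
    """

    def __init__(self, alpha: float = 0.1):
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x).astype(DTYPE)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, self.alpha * gy).astype(DTYPE)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        x6 = x[:, :h2 * 2, :w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
        a, b = x6[:, :, 0], x6[:, :, 1]
        self._row = b >= a                       # ties -> second row, fixed rule
        m1 = np.where(self._row, b, a)           # (n, h2, w2, 2, c)
        u, v = m1[:, :, :, 0], m1[:, :, :, 1]
        self._col = v >= u
        self._xshape = x.shape
        return np.where(self._col, v, u)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        h2, w2 = h // 2, w // 2
        z = np.zeros_like(gy)
        dm1 = np.stack([np.where(self._col, z, gy),
                        np.where(self._col, gy, z)], axis=3)
        zm = np.zeros_like(dm1)
        dx6 = np.stack([np.where(self._row, zm, dm1),
                        np.where(self._row, dm1, zm)], axis=2)
        dx = dx6.reshape(n, h2 * 2, w2 * 2, c)
        if (h2 * 2, w2 * 2) != (h, w):
            full = np.zeros((n, h, w, c), dtype=DTYPE)
            full[:, :h2 * 2, :w2 * 2, :] = dx
            return full
        return dx


class GlobalAvgPool(Layer):
    """Mean over the spatial axes: (N, H, W, C) -> (N, C).

    Summarizes each feature map by its average response, discarding
    spatial layout — the head sees texture statistics, not geometry.
    """

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        return np.broadcast_to(gy[:, None, None, :] / (h * w),
                               self._xshape).astype(DTYPE)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return np.ascontiguousarray(x).reshape(x.shape[0], -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params = [w.astype(DTYPE), np.zeros(n_out, dtype=DTYPE)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = np.ascontiguousarray(x, dtype=DTYPE)
        return self._x @ self.params[0] + self.params[1]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = np.ascontiguousarray(gy, dtype=DTYPE)
        self.grads[0][...] = self._x.T @ gy
        self.grads[1][...] = gy.sum(axis=0)
        return gy @ self.params[0].T


class Sequential:
    """A plain feed-forward stack of layers."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state, strict=True):
            p[...] = s


class Adam:
    """Adam with the standard default hyperparameters."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
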