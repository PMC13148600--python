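"""Minimal reverse-mode neural-network layers on numpy.

Only the building blocks needed by the coordinate field network and the
residual U-Net baseline are provided: dense and 2-D convolution layers
with explicit backward passes, swish/sigmoid/leaky-ReLU activations,
average-pool / nearest-upsample resampling and an Adam optimizer.
Forward passes cache whatever the backward pass needs; ``backward``
accumulates parameter gradients into ``layer.grads`` and returns the
input cotangent.
"""

from __future__ import annotations

import numba
import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    # exp overflow for very negative x saturates to the correct limit 0
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


@numba.njit(cache=True, fastmath=True)
def _swish_fwd(z, s, out):
    # fused: s = sigmoid(z), out = z * s (single memory pass)
    for i in range(z.size):
        si = 1.0 / (1.0 + np.exp(-z[i]))
        s[i] = si
        out[i] = z[i] * si


@numba.njit(cache=True, fastmath=True)
def _swish_bwd(g, z, s):
    # fused in-place: g *= s * (1 + z * (1 - s))
    for i in range(g.size):
        g[i] *= s[i] * (1.0 + z[i] * (1.0 - s[i]))


def swish(x: np.ndarray) -> np.ndarray:
    return x * sigmoid(x)


def swish_grad(x: np.ndarray) -> np.ndarray:
    s = sigmoid(x)
    return s * (1.0 + x * (1.0 - s))


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class Dense(Layer):
    """Fully connected layer y = x W + b with optional activation."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int,
                 activation: str | None = None, dtype=np.float64,
                 needs_input_grad: bool = True):
        self.W = glorot_uniform(rng, n_in, n_out, (n_in, n_out), dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.activation = activation
        self.needs_input_grad = needs_input_grad
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "swish":
            self._z = z
            self._s = np.empty_like(z)  # sigmoid cache for the backward pass
            out = np.empty_like(z)
            _swish_fwd(z.ravel(), self._s.ravel(), out.ravel())
            return out
        if self.activation == "sigmoid":
            self._out = sigmoid(z)
            return self._out
        return z

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.activation == "swish":
            g = np.ascontiguousarray(g)
            _swish_bwd(g.ravel(), self._z.ravel(), self._s.ravel())
        elif self.activation == "sigmoid":
            g = g * self._out * (1.0 - self._out)
        self.grads[0] += self._x.T @ g
        self.grads[1] += g.sum(axis=0)
        if not self.needs_input_grad:
            return g  # input is a fixed encoding; its cotangent is unused
        return g @ self.W.T


def im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H, W, C*k*k) patches with zero 'same' padding."""
    b, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = np.empty((b, h, w, c, k, k), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[..., i, j] = xp[:, :, i:i + h, j:j + w].transpose(0, 2, 3, 1)
    return cols.reshape(b, h, w, c * k * k)


def col2im(cols: np.ndarray, shape: tuple, k: int) -> np.ndarray:
    b, c, h, w = shape
    p = k // 2
    xp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    cols = cols.reshape(b, h, w, c, k, k)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + h, j:j + w] += cols[..., i, j].transpose(0, 3, 1, 2)
    return xp[:, :, p:p + h, p:p + w]


class Conv2d(Layer):
    """k x k 'same' convolution (stride 1) with optional activation."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int, k: int = 3,
                 activation: str | None = None, dtype=np.float64,
                 leaky_slope: float = 0.1):
        fan_in, fan_out = c_in * k * k, c_out * k * k
        self.W = glorot_uniform(rng, fan_in, fan_out, (c_in * k * k, c_out), dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.k = k
        self.activation = activation
        self.leaky_slope = leaky_slope
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        cols = im2col(x, self.k)
        self._cols = cols.reshape(-1, cols.shape[-1])
        z = (self._cols @ self.W + self.b)
        b, c, h, w = x.shape
        z = z.reshape(b, h, w, -1).transpose(0, 3, 1, 2)
        self._z = z
        if self.activation == "swish":
            return swish(z)
        if self.activation == "sigmoid":
            self._out = sigmoid(z)
            return self._out
        if self.activation == "leaky_relu":
            return np.where(z >= 0, z, self.leaky_slope * z)
        return z

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.activation == "swish":
            g = g * swish_grad(self._z)
        elif self.activation == "sigmoid":
            g = g * self._out * (1.0 - self._out)
        elif self.activation == "leaky_relu":
            g = np.where(self._z >= 0, g, self.leaky_slope * g)
        b, c_out, h, w = g.shape
        gm = g.transpose(0, 2, 3, 1).reshape(-1, c_out)
        self.grads[0] += self._cols.T @ gm
        self.grads[1] += gm.sum(axis=0)
        gcols = gm @ self.W.T
        return col2im(gcols.reshape(b, h, w, -1), self._xshape, self.k)


class AvgPool2(Layer):
    """2x2 average pooling (dimensions must be even)."""

    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        return np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0


class UpsampleNearest2(Layer):
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, c, h, w = g.shape
        return g.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adam optimizer over an explicit (params, grads) list."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
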