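"""Minimal NumPy neural-network layers for the counting network.

The counting network is tiny (seven 3x3 convolutions, a few thousand
parameters), so it is implemented directly on NumPy arrays with explicit
backprop.  Convolution is evaluated as nine shifted matrix products against
BLAS, which keeps both time and memory modest on a single CPU at the patch
sizes used here.  Layout is NHWC throughout, float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3x3", "Linear", "FeatureNorm", "relu", "relu_grad", "Adam"]


class Conv3x3:
    """3x3 convolution, stride 1, zero same-padding, NHWC.

    He-normal initialization.  The convolution is evaluated as nine shifted
    GEMMs against views of the padded input, which benchmarks faster here
    than explicit im2col lowering (the lowering's scattered writes dominate
    at these channel counts).
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 weight_scale: float = 1.0, bias_init: float = 0.0):
        std = weight_scale * np.sqrt(2.0 / (9 * c_in))
        self.W = rng.normal(0.0, std, size=(3, 3, c_in, c_out)).astype(np.float32)
        self.b = np.full(c_out, bias_init, dtype=np.float32)
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, H, W, _ = x.shape
        c_out = self.W.shape[3]
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        y = np.empty((B, H, W, c_out), dtype=np.result_type(x, self.W))
        y[...] = self.b
        for i in range(3):
            for j in range(3):
                y += xp[:, i : i + H, j : j + W, :] @ self.W[i, j]
        if train:
            self._xp = xp
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        B, H, W, c_out = dy.shape
        c_in = self.W.shape[2]
        dy2 = dy.reshape(-1, c_out)
        self.dW = np.empty_like(self.W)
        self.db = dy2.sum(axis=0)
        dxp = np.zeros_like(xp)
        for i in range(3):
            for j in range(3):
                slab = xp[:, i : i + H, j : j + W, :].reshape(-1, c_in)
                self.dW[i, j] = slab.T @ dy2
                dxp[:, i : i + H, j : j + W, :] += (dy2 @ self.W[i, j].T).reshape(
                    B, H, W, c_in
                )
        self._xp = None
        return dxp[:, 1:-1, 1:-1, :]


class Linear:
    """Fully connected layer."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, std, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        self._x = None
        return dy @ self.W.T


class FeatureNorm:
    """Per-feature standardization of a (B, F) batch, no learned affine.

    Pooled convolutional features arrive with large offsets and tiny
    variance, which stalls a linear readout trained by gradient descent;
    standardizing them makes the following linear layer's problem well
    conditioned.  Batch statistics are used during training and folded into
    running averages for inference (momentum 0.1).
    """

    def __init__(self, n_features: int, eps: float = 1e-6, momentum: float = 0.1):
        self.running_mean = np.zeros(n_features, dtype=np.float32)
        self.running_var = np.ones(n_features, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum
        self._cache: tuple | None = None

    def params(self):
        return []

    def grads(self):
        return []

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.running_mean *= 1 - m
            self.running_mean += m * mu
            self.running_var *= 1 - m
            self.running_var += m * var
        else:
            mu, var = self.running_mean, self.running_var
        sd = np.sqrt(var + self.eps)
        y = (x - mu) / sd
        if train:
            self._cache = (y, sd)
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y, sd = self._cache
        self._cache = None
        dx = (dy - dy.mean(axis=0) - y * (dy * y).mean(axis=0)) / sd
        return dx.astype(np.float32)


def relu(x: np.ndarray) -> np.ndarray:
    """In-place ReLU (the conv output it receives is always freshly owned)."""
    return np.maximum(x, 0.0, out=x)


def relu_grad(y: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Gradient through ReLU given its *output* y; modifies dy in place."""
    dy *= y > 0
    return dy


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place updates)."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
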