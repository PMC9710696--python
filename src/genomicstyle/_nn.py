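"""Minimal NumPy neural-network primitives for the feature-extraction CNN.

Implements exactly what the 1-D species-classification network needs:
same-padded stride-1 convolution, batch normalization with running
statistics, ReLU, width-``p`` max pooling, global average pooling, a dense
layer, softmax cross-entropy and Adam.  Layers expose ``forward(x, train)``
/ ``backward(dy)`` and keep parameter gradients alongside the parameters so
the optimizer can walk them generically.

All activations are float32 in channels-last layout (batch, length,
channels): a stride-1 convolution with filter width ``d`` is then a sum of
``d`` shifted (B*L, C_in) @ (C_in, C_out) matmuls, which keeps every
operation a large contiguous BLAS call instead of an im2col gather.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: parameterless layers only implement forward/backward."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def state(self) -> dict[str, np.ndarray]:
        """Non-trainable buffers (e.g. batch-norm running statistics)."""
        return {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Stride-1 cross-correlation with same padding.

    ``W`` has shape (d, n_in, n_out); input (B, L, n_in) maps to
    (B, L, n_out).  Padding puts floor((d-1)/2) zeros on the left so the
    output length always equals the input length:
    y[b, t, o] = b[o] + sum_{k, c} x[b, t + k - pad_left, c] * W[k, c, o].
    """

    def __init__(self, n_in: int, n_out: int, d: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in * d))  # He initialization for ReLU nets
        self.W = (rng.standard_normal((d, n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.d = d
        self.pad_left = (d - 1) // 2
        self.pad_right = d - 1 - self.pad_left

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        y = np.empty((B, L, self.W.shape[2]), dtype=np.float32)
        y[...] = self.b
        for k in range(self.d):
            y += xp[:, k : k + L, :] @ self.W[k]
        if train:
            self._xp = xp
            self._L = L
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        L = self._L
        xp = self._xp
        dy2 = dy.reshape(-1, dy.shape[2])
        self.db[...] = dy2.sum(axis=0)
        dxp = np.zeros_like(xp)
        for k in range(self.d):
            xk = xp[:, k : k + L, :].reshape(-1, xp.shape[2])
            self.dW[k] = xk.T @ dy2
            dxp[:, k : k + L, :] += dy @ self.W[k].T
        self._xp = None
        return dxp[:, self.pad_left : self.pad_left + L, :]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_channels, dtype=np.float32)
        self.beta = np.zeros(n_channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_channels, dtype=np.float32)
        self.running_var = np.ones(n_channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean.astype(np.float32)) * inv_sd
        if train:
            self._xhat = xhat
            self._inv_sd = inv_sd
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dgamma[...] = (dy * self._xhat).sum(axis=(0, 1))
        self.dbeta[...] = dy.sum(axis=(0, 1))
        # standard batch-norm backward through the batch statistics
        dxhat = dy * self.gamma
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 1))
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 1))
        ) * self._inv_sd
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool1d(Layer):
    """Non-overlapping max pooling of width ``p`` (drops a trailing remainder)."""

    def __init__(self, p: int):
        self.p = p

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = x.shape
        Lp = (L // self.p) * self.p
        if self.p == 2:  # fast path: the default architecture pools by 2
            a, b = x[:, 0:Lp:2, :], x[:, 1:Lp:2, :]
            y = np.maximum(a, b)
            if train:
                self._left_wins = a >= b  # ties route to the earlier position
                self._in_shape = (B, L, C)
            return y
        blocks = x[:, :Lp, :].reshape(B, Lp // self.p, self.p, C)
        y = blocks.max(axis=2)
        if train:
            self._argmax = blocks.argmax(axis=2)
            self._in_shape = (B, L, C)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L, C = self._in_shape
        n_blocks = dy.shape[1]
        dx = np.zeros((B, L, C), dtype=np.float32)
        if self.p == 2:
            dx[:, 0 : 2 * n_blocks : 2, :] = np.where(self._left_wins, dy, 0.0)
            dx[:, 1 : 2 * n_blocks : 2, :] = np.where(self._left_wins, 0.0, dy)
            self._left_wins = None
            return dx
        dxb = dx[:, : n_blocks * self.p, :].reshape(B, n_blocks, self.p, C)
        np.put_along_axis(dxb, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        self._argmax = None
        return dx


class GlobalAvgPool(Layer):
    """(B, L, C) -> (B, C) mean over positions."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, None, :] / self._L, self._L, axis=1).astype(np.float32)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_out, n_in)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[...] = dy.T @ self._x
        self.db[...] = dy.sum(axis=0)
        dx = dy @ self.W
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), targets], 1e-300)).mean()
    grad = p
    grad[np.arange(n), targets] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class Adam:
    """Adam over the parameter dictionaries of a list of layers."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params()]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in l.params().items()} for l in self.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in l.params().items()} for l in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            grads = layer.grads()
            for key, param in layer.params().items():
                g = grads[key]
                m[key] += (1.0 - self.beta1) * (g - m[key])
                v[key] += (1.0 - self.beta2) * (g * g - v[key])
                param -= self.lr * (m[key] / bc1) / (np.sqrt(v[key] / bc2) + self.eps)
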