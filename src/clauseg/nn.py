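"""Minimal 2D conv-net engine in NumPy.

Self-contained building blocks (stride-1 'same' convolution, 2x2 max
pooling, nearest-neighbour upsampling, ReLU/sigmoid) with hand-derived
backward passes, plus an Adam optimiser.  Everything is deterministic
given the initialisation seed and input order, which keeps training runs
exactly reproducible on any machine; gradients are validated against
finite differences in the test suite.

Internally arrays are channels-last (N, H, W, C): convolution is computed
as k*k shifted GEMMs, which keeps the inner dimension contiguous and
avoids im2col copies.  Even kernel sizes pad one pixel less on the
low-index side, mirroring the common 'same' convention.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "MaxPool2", "Upsample2", "sigmoid", "Adam"]


class Conv2D:
    """Stride-1 'same' convolution with bias, on (N, H, W, C) arrays.

    Weights have shape (k, k, c_in, c_out) and are He-initialised.
    ``trainable=False`` freezes the layer (its parameters drop out of the
    trainable count and receive no updates).
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = rng.normal(0.0, std, size=(k, k, cin, cout)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.k = k
        self.pad_lo = (k - 1) // 2
        self.pad_hi = k // 2
        self.trainable = True
        self.dW = None
        self.db = None
        self._xp = None

    def n_params(self) -> int:
        return int(self.W.size + self.b.size) if self.trainable else 0

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        k, pl, ph = self.k, self.pad_lo, self.pad_hi
        if k == 1:
            y = x @ self.W[0, 0] + self.b
            self._xp = x if keep else None
            self._hw = x.shape[1:3]
            return y
        xp = np.pad(x, ((0, 0), (pl, ph), (pl, ph), (0, 0)))
        n, hp, wp, _ = xp.shape
        h, w = hp - k + 1, wp - k + 1
        y = np.zeros((n, h, w, self.W.shape[3]), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                y += xp[:, i:i + h, j:j + w, :] @ self.W[i, j]
        y += self.b
        self._xp = xp if keep else None
        self._hw = (h, w)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, pl = self.k, self.pad_lo
        h, w = self._hw
        self.db = dy.sum(axis=(0, 1, 2))
        if k == 1:
            x = self._xp
            self.dW = (np.tensordot(x, dy, axes=([0, 1, 2], [0, 1, 2]))
                       [None, None])
            dx = dy @ self.W[0, 0].T
            self._xp = None
            return dx
        xp = self._xp
        cin = self.W.shape[2]
        dW = np.empty_like(self.W)
        dxp = np.zeros_like(xp)
        dy = np.ascontiguousarray(dy)
        dy2 = dy.reshape(-1, dy.shape[3])
        for i in range(k):
            for j in range(k):
                xs = np.ascontiguousarray(xp[:, i:i + h, j:j + w, :])
                dW[i, j] = xs.reshape(-1, cin).T @ dy2
                dxp[:, i:i + h, j:j + w, :] += dy @ self.W[i, j].T
        self.dW = dW
        self._xp = None
        return np.ascontiguousarray(dxp[:, pl:pl + h, pl:pl + w, :])


class ReLU:
    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        y = np.maximum(x, 0)
        self._pos = (x > 0) if keep else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = dy * self._pos
        self._pos = None
        return out


class MaxPool2:
    """2x2 max pooling with stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xr = x[:, :h2 * 2, :w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
        xf = xr.transpose(0, 1, 3, 2, 4, 5).reshape(n, h2, w2, 4, c)
        idx = xf.argmax(axis=3)
        y = np.take_along_axis(xf, idx[:, :, :, None], axis=3)[:, :, :, 0]
        if keep:
            self._idx = idx
            self._in_shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dxf = np.zeros((n, h2, w2, 4, c), dtype=dy.dtype)
        np.put_along_axis(dxf, self._idx[:, :, :, None], dy[:, :, :, None], axis=3)
        dx = np.zeros((n, h, w, c), dtype=dy.dtype)
        dx[:, :h2 * 2, :w2 * 2, :] = (
            dxf.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h2 * 2, w2 * 2, c)
        )
        self._idx = None
        return dx


class Upsample2:
    """Nearest-neighbour 2x upsampling (parameter-free)."""

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adaptive moment estimation over a fixed list of Conv2D layers."""

    def __init__(self, layers, lr: float = 2e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if isinstance(l, Conv2D)]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in self.layers]
        self.v = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for i, layer in enumerate(self.layers):
            if not layer.trainable or layer.dW is None:
                continue
            for p, g, m, v in ((layer.W, layer.dW, self.m[i][0], self.v[i][0]),
                               (layer.b, layer.db, self.m[i][1], self.v[i][1])):
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
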