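"""Minimal CPU neural-network primitives (forward + backprop) in numpy.

Just enough machinery for the small Siamese CNN and the one-layer models in
this package: stride-1 'same' convolution via im2col, ReLU, 2x2 max pooling,
adaptive average pooling, dense layers, a numerically stable sigmoid /
binary-cross-entropy pair, and Adam.  Everything runs in float32 and is
bit-deterministic given the rng used for initialization and data order.

Shapes follow the (N, C, H, W) convention.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "AdaptiveAvgPool",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "sigmoid",
    "bce_with_logits",
]

DTYPE = np.float32


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out.astype(z.dtype)


def bce_with_logits(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    z64 = z.astype(np.float64)
    loss = np.mean(np.maximum(z64, 0) - z64 * t + np.log1p(np.exp(-np.abs(z64))))
    grad = (sigmoid(z) - t.astype(z.dtype)) / z.size
    return float(loss), grad.astype(z.dtype)


class Layer:
    params: list
    grads: list

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Stride-1 convolution with 'same' zero padding, kernel k x k."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.pad = k // 2
        fan_in = in_ch * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, fan_in))
        self.W = w.astype(DTYPE)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.grads = [self.dW, self.db]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.empty((n, c, k, k, h, w), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i : i + h, j : j + w]
        return cols.reshape(n, c * k * k, h * w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = self._im2col(x.astype(DTYPE))
        n, _, h, w = x.shape
        y = np.matmul(self.W, self._cols) + self.b[None, :, None]
        return y.reshape(n, self.out_ch, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        k, p = self.k, self.pad
        d = dout.reshape(n, self.out_ch, h * w).astype(DTYPE)
        self.dW[...] = np.einsum("nol,nkl->ok", d, self._cols)
        self.db[...] = d.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T, d).reshape(n, c, k, k, h, w)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/columns are cropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = h // 2, w // 2
        self._in_shape = x.shape
        xv = x[:, :, : 2 * oh, : 2 * ow]
        win = (
            xv.reshape(n, c, oh, 2, ow, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, oh, ow, 4)
        )
        self._idx = win.argmax(axis=-1)
        return np.take_along_axis(win, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        oh, ow = h // 2, w // 2
        dwin = np.zeros((n, c, oh, ow, 4), dtype=dout.dtype)
        np.put_along_axis(dwin, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=dout.dtype)
        dx[:, :, : 2 * oh, : 2 * ow] = (
            dwin.reshape(n, c, oh, ow, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, 2 * oh, 2 * ow)
        )
        return dx


class AdaptiveAvgPool(Layer):
    """Average pooling to a fixed (out_h, out_w), any input size.

    Bin i covers rows [floor(i*H/out), ceil((i+1)*H/out)); when the output is
    larger than the input, bins overlap / repeat, so the layer also upsamples
    gracefully.
    """

    def __init__(self, out_h: int, out_w: int):
        super().__init__()
        self.out_h, self.out_w = out_h, out_w

    @staticmethod
    def _edges(size: int, out: int) -> list[tuple[int, int]]:
        return [
            (int(np.floor(i * size / out)), int(np.ceil((i + 1) * size / out)))
            for i in range(out)
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._in_shape = x.shape
        self._he = self._edges(h, self.out_h)
        self._we = self._edges(w, self.out_w)
        y = np.empty((n, c, self.out_h, self.out_w), dtype=x.dtype)
        for i, (a, b) in enumerate(self._he):
            for j, (u, v) in enumerate(self._we):
                y[:, :, i, j] = x[:, :, a:b, u:v].mean(axis=(2, 3))
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        for i, (a, b) in enumerate(self._he):
            for j, (u, v) in enumerate(self._we):
                dx[:, :, a:b, u:v] += (dout[:, :, i, j] / ((b - a) * (v - u)))[
                    :, :, None, None
                ]
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.grads = [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x.astype(DTYPE)
        return self._x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = dout.astype(DTYPE)
        self.dW[...] = self._x.T @ d
        self.db[...] = d.sum(axis=0)
        return d @ self.W.T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)
        for lyr in self.layers:
            self.params.extend(lyr.params)
            self.grads.extend(lyr.grads)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lyr in self.layers:
            x = lyr.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for lyr in reversed(self.layers):
            dout = lyr.backward(dout)
        return dout

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def load_state(self, arrays) -> None:
        for p, a in zip(self.params, arrays, strict=True):
            p[...] = a


class Adam:
    def __init__(
        self,
        params: list,
        grads: list,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
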