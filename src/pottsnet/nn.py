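"""Minimal CNN building blocks with exact periodic (circular) boundary
handling, written on top of NumPy.

Every convolution here is circular: the kernel wraps around the lattice
edges, matching the torus topology of the simulator.  Circular convolution
makes the forward and backward passes expressible with ``np.roll`` and BLAS
matmuls, so no padding buffers or index bookkeeping are needed and the
network is exactly shift-equivariant (up to pooling alignment).

Layers follow a uniform contract: ``forward(x, train)`` caches what the
backward pass needs, ``backward(dy)`` returns dx and fills ``grads`` (same
keys as ``params``).  Arrays are NCHW float32 by default.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError


def periodic_pad(image: np.ndarray, width: int) -> np.ndarray:
    """Pad the last two axes by ``width`` with wrapped (torus) values.

    Every padded border value equals the value at the opposite edge; width 0
    returns an unchanged copy.
    """
    if width < 0:
        raise ParameterError("pad width must be >= 0")
    image = np.asarray(image)
    h, w = image.shape[-2], image.shape[-1]
    if width >= h or width >= w:
        raise ParameterError("pad width must be smaller than the image extent")
    if width == 0:
        return image.copy()
    pad = [(0, 0)] * (image.ndim - 2) + [(width, width), (width, width)]
    return np.pad(image, pad, mode="wrap")


class Layer:
    """Base: parameterless layer."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2dPeriodic(Layer):
    """k x k circular convolution, NCHW, stride 1, He-normal init."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        if k % 2 != 1:
            raise ParameterError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.params = {"w": w.astype(dtype), "b": np.zeros(c_out, dtype=dtype)}
        self._rel = [a - k // 2 for a in range(k)]
        self._cache = None

    def _im2col(self, x):
        n, c, h, w = x.shape
        k = self.k
        cols = np.empty((n, c, k * k, h, w), dtype=x.dtype)
        m = 0
        for ra in self._rel:
            for rb in self._rel:
                cols[:, :, m] = np.roll(x, (-ra, -rb), axis=(2, 3))
                m += 1
        return cols.reshape(n, c * k * k, h * w)

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        cols = self._im2col(x)
        y = self.params["w"] @ cols + self.params["b"][:, None]
        self._cache = (cols, (n, c, h, w)) if train else None
        return y.reshape(n, self.c_out, h, w)

    def backward(self, dy):
        cols, (n, c, h, w) = self._cache
        f = h * w
        dyf = dy.reshape(n, self.c_out, f)
        a = dyf.transpose(1, 0, 2).reshape(self.c_out, n * f)
        b = cols.transpose(1, 0, 2).reshape(cols.shape[1], n * f)
        self.grads["w"] = a @ b.T
        self.grads["b"] = dyf.sum(axis=(0, 2))
        dcols = (self.params["w"].T @ dyf).reshape(n, c, self.k * self.k, h, w)
        dx = np.zeros((n, c, h, w), dtype=dy.dtype)
        m = 0
        for ra in self._rel:
            for rb in self._rel:
                dx += np.roll(dcols[:, :, m], (ra, rb), axis=(2, 3))
                m += 1
        return dx


class PReLU(Layer):
    """Per-channel parametric ReLU: y = x if x > 0 else a * x."""

    def __init__(self, channels: int, init: float = 0.25, dtype=np.float32):
        super().__init__()
        self.params = {"a": np.full(channels, init, dtype=dtype)}
        self._cache = None

    def forward(self, x, train=False):
        neg = x <= 0
        a = self.params["a"][None, :, None, None]
        y = np.where(neg, a * x, x)
        self._cache = (x, neg) if train else None
        return y

    def backward(self, dy):
        x, neg = self._cache
        a = self.params["a"][None, :, None, None]
        self.grads["a"] = np.where(neg, dy * x, 0.0).sum(axis=(0, 2, 3))
        return np.where(neg, a * dy, dy)


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.params = {"gamma": np.ones(channels, dtype=dtype),
                       "beta": np.zeros(channels, dtype=dtype)}
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, train=False):
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.astype(np.float64))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.astype(np.float64))
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
            self._cache = (xhat, invstd)
            return g * xhat + b
        invstd = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None, None]) \
            * invstd[None, :, None, None]
        return (g * xhat.astype(x.dtype) + b)

    def backward(self, dy):
        xhat, invstd = self._cache
        g = self.params["gamma"][None, :, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dy.sum(axis=(0, 2, 3))
        dx = (invstd[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        return dx.astype(dy.dtype)


class AvgPool2(Layer):
    """2x2 average pooling (the lattice side must be even)."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy):
        return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) * 0.25


class BilinearUp2(Layer):
    """Factor-2 bilinear upsampling with periodic wrap.

    out[2i] = 0.75 x[i] + 0.25 x[i-1]; out[2i+1] = 0.75 x[i] + 0.25 x[i+1]
    (both axes), which is the adjoint-consistent periodic analog of
    align_corners=False bilinear interpolation.
    """

    @staticmethod
    def _up_axis(x, axis):
        even = 0.75 * x + 0.25 * np.roll(x, 1, axis=axis)
        odd = 0.75 * x + 0.25 * np.roll(x, -1, axis=axis)
        out = np.stack([even, odd], axis=axis + 1)
        shape = list(x.shape)
        shape[axis] *= 2
        return out.reshape(shape)

    @staticmethod
    def _down_axis(d, axis):
        # adjoint of _up_axis
        shape = list(d.shape)
        shape[axis] //= 2
        pairs = d.reshape(shape[:axis] + [shape[axis], 2] + shape[axis + 1:])
        de = np.take(pairs, 0, axis=axis + 1)
        do = np.take(pairs, 1, axis=axis + 1)
        return (0.75 * (de + do) + 0.25 * np.roll(de, -1, axis=axis)
                + 0.25 * np.roll(do, 1, axis=axis))

    def forward(self, x, train=False):
        return self._up_axis(self._up_axis(x, 2), 3)

    def backward(self, dy):
        return self._down_axis(self._down_axis(dy, 3), 2)


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam over a list of (params, grads) dict pairs from layers."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.slots = [(lay.params, lay.grads) for lay in layers if lay.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in p.items()} for p, _ in self.slots]
        self.v = [{k: np.zeros_like(v) for k, v in p.items()} for p, _ in self.slots]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.slots, self.m, self.v):
            for k in p:
                grad = g[k].astype(p[k].dtype)
                m[k] = self.b1 * m[k] + (1 - self.b1) * grad
                v[k] = self.b2 * v[k] + (1 - self.b2) * grad * grad
                p[k] -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)
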