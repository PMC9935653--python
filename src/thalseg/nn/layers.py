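"""Minimal 3D CNN building blocks with explicit forward/backward passes.

Tensors are single samples of shape (C, D, H, W). Each layer caches what its
backward pass needs during forward; calling backward accumulates parameter
gradients into ``Param.grad``. Convolutions are evaluated as im2col matrix
products so the heavy lifting stays inside BLAS.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A learnable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def params(self):
        return []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, stride 1, 'same' zero padding, kernel 1 or 3."""

    def __init__(self, c_in, c_out, kernel=3, rng=None, dtype=np.float32):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.dtype = dtype
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in) + (kernel,) * 3)
        self.W = Param(w.astype(dtype), "conv.W")
        self.b = Param(np.zeros(c_out, dtype=dtype), "conv.b")
        self._cols = None
        self._shape = None

    def params(self):
        return [self.W, self.b]

    def _im2col(self, x):
        c, d, h, w = x.shape
        k, p = self.k, self.k // 2
        if k == 1:
            return x.reshape(c, -1)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        cols = np.empty((c, k, k, k, d, h, w), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    np.copyto(cols[:, i, j, l], xp[:, i : i + d, j : j + h, l : l + w])
        return cols.reshape(c * k**3, -1)

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=self.dtype)
        self._shape = x.shape
        cols = self._im2col(x)
        self._cols = cols
        wmat = self.W.value.reshape(self.c_out, -1)
        y = wmat @ cols + self.b.value[:, None]
        return y.reshape((self.c_out,) + x.shape[1:])

    def backward(self, dy):
        c, d, h, w = self._shape
        k, p = self.k, self.k // 2
        dy_mat = np.ascontiguousarray(dy, dtype=self.dtype).reshape(self.c_out, -1)
        self.W.grad += (dy_mat @ self._cols.T).reshape(self.W.value.shape)
        self.b.grad += dy_mat.sum(axis=1)
        dcols = self.W.value.reshape(self.c_out, -1).T @ dy_mat
        if k == 1:
            return dcols.reshape(self._shape)
        dcols = dcols.reshape(c, k, k, k, d * h * w)
        dxp = np.zeros((c, d + 2 * p, h + 2 * p, w + 2 * p), dtype=self.dtype)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dxp[:, i : i + d, j : j + h, l : l + w] += dcols[:, i, j, l, :].reshape(c, d, h, w)
        return dxp[:, p : p + d, p : p + h, p : p + w]


class InstanceNorm3d(Layer):
    """Per-channel normalization over the spatial extent of a single sample."""

    def __init__(self, channels, eps=1e-5, dtype=np.float32):
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=dtype), "in.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), "in.beta")
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        c = x.shape[0]
        flat = x.reshape(c, -1)
        mu = flat.mean(axis=1, keepdims=True)
        var = flat.var(axis=1, keepdims=True)
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (flat - mu) * ivar
        self._cache = (xhat, ivar, x.shape)
        y = self.gamma.value[:, None] * xhat + self.beta.value[:, None]
        return y.reshape(x.shape).astype(x.dtype)

    def backward(self, dy):
        xhat, ivar, shape = self._cache
        c = shape[0]
        dy_flat = dy.reshape(c, -1)
        n = dy_flat.shape[1]
        self.gamma.grad += (dy_flat * xhat).sum(axis=1)
        self.beta.grad += dy_flat.sum(axis=1)
        dxhat = dy_flat * self.gamma.value[:, None]
        dx = (
            ivar
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=1, keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=1, keepdims=True)
            )
        )
        return dx.reshape(shape)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class AvgPool2(Layer):
    """2x2x2 average pooling (requires even spatial dimensions)."""

    def forward(self, x):
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {x.shape}")
        self._shape = x.shape
        return x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))

    def backward(self, dy):
        c, d, h, w = self._shape
        up = np.repeat(np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2), 2, axis=3)
        return (up / 8.0).astype(dy.dtype)


class Upsample2(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x):
        self._shape = x.shape
        return np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)

    def backward(self, dy):
        c, d, h, w = self._shape
        return dy.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6))


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class ResBlock(Layer):
    """conv-IN-ReLU-conv-IN plus a (projected) shortcut, ReLU on the sum."""

    def __init__(self, c_in, c_out, rng=None, dtype=np.float32):
        self.main = Sequential(
            Conv3d(c_in, c_out, 3, rng, dtype),
            InstanceNorm3d(c_out, dtype=dtype),
            ReLU(),
            Conv3d(c_out, c_out, 3, rng, dtype),
            InstanceNorm3d(c_out, dtype=dtype),
        )
        self.proj = Conv3d(c_in, c_out, 1, rng, dtype) if c_in != c_out else None
        self.out_relu = ReLU()

    def params(self):
        ps = self.main.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x):
        shortcut = self.proj.forward(x) if self.proj is not None else x
        return self.out_relu.forward(self.main.forward(x) + shortcut)

    def backward(self, dy):
        dy = self.out_relu.backward(dy)
        dx = self.main.backward(dy)
        if self.proj is not None:
            dx = dx + self.proj.backward(dy)
        else:
            dx = dx + dy
        return dx
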