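"""Minimal layer zoo with explicit forward/backward passes.

Everything is plain numpy: convolutions go through im2col + BLAS matmul, and
every layer caches what its backward pass needs.  Shapes follow the usual
channels-first convention: (N, C, L) for 1-D signals, (N, C, H, W) for 2-D.
Parameters live in :class:`Param` holders (value + gradient accumulator) so an
optimizer can walk the tree generically.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "Conv1d",
    "Conv2d",
    "BatchNorm",
    "MaxPool1d",
    "MaxPool2d",
    "ReLU",
    "Dropout",
    "Flatten",
    "Residual",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    name: str = ""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float32):
        self.w = Param(_he_init(rng, (d_in, d_out), d_in, dtype))
        self.b = Param(np.zeros(d_out, dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class Conv1d(Layer):
    """'same'-padded 1-D convolution (odd kernel), stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, dtype=np.float32):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.w = Param(_he_init(rng, (c_out, c_in * k), c_in * k, dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        n, c, length = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)  # (N,C,L,k)
        cols = win.transpose(0, 2, 1, 3).reshape(n * length, c * self.k)
        self._cols, self._shape = cols, (n, c, length)
        out = cols @ self.w.value.T + self.b.value
        return out.reshape(n, length, self.c_out).transpose(0, 2, 1)

    def backward(self, dout):
        n, c, length = self._shape
        dmat = dout.transpose(0, 2, 1).reshape(n * length, self.c_out)
        self.w.grad += dmat.T @ self._cols
        self.b.grad += dmat.sum(axis=0)
        dcols = (dmat @ self.w.value).reshape(n, length, c, self.k).transpose(0, 2, 1, 3)
        p = self.k // 2
        dxp = np.zeros((n, c, length + 2 * p), dtype=dout.dtype)
        for i in range(self.k):
            dxp[:, :, i : i + length] += dcols[:, :, :, i]
        return dxp[:, :, p : p + length]


class Conv2d(Layer):
    """'same'-padded square 2-D convolution (odd kernel), stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, dtype=np.float32):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.w = Param(_he_init(rng, (c_out, c_in * k * k), c_in * k * k, dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        n, c, hh, ww = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * hh * ww, c * k * k)
        self._cols, self._shape = cols, (n, c, hh, ww)
        out = cols @ self.w.value.T + self.b.value
        return out.reshape(n, hh, ww, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, c, hh, ww = self._shape
        k, p = self.k, self.k // 2
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * hh * ww, self.c_out)
        self.w.grad += dmat.T @ self._cols
        self.b.grad += dmat.sum(axis=0)
        dcols = (
            (dmat @ self.w.value)
            .reshape(n, hh, ww, c, k, k)
            .transpose(0, 3, 1, 2, 4, 5)
        )
        dxp = np.zeros((n, c, hh + 2 * p, ww + 2 * p), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + hh, j : j + ww] += dcols[:, :, :, :, i, j]
        return dxp[:, :, p : p + hh, p : p + ww]


class BatchNorm(Layer):
    """Per-channel batch normalization over all non-channel axes."""

    def __init__(self, channels: int, dtype=np.float32, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.run_mean = np.zeros(channels, dtype=dtype)
        self.run_var = np.ones(channels, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._initialized = False

    def params(self):
        return [self.gamma, self.beta]

    def _bshape(self, ndim):
        return (1, -1) + (1,) * (ndim - 2)

    def forward(self, x, train):
        axes = (0,) + tuple(range(2, x.ndim))
        shape = self._bshape(x.ndim)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if not self._initialized:
                # seed the running stats with the first batch so eval-mode
                # outputs are sane from the start of training
                self.run_mean, self.run_var = mean.copy(), var.copy()
                self._initialized = True
            else:
                self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
                self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        self._xhat, self._inv, self._axes = xhat, inv, axes
        self._m, self._train = x.size // x.shape[1], train
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, dout):
        shape = self._bshape(dout.ndim)
        axes, m = self._axes, self._m
        self.gamma.grad += (dout * self._xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value.reshape(shape)
        if not self._train:
            # eval mode: mean/var are constants, the map is affine
            return dxhat * self._inv.reshape(shape)
        t1 = dxhat.sum(axis=axes, keepdims=True)
        t2 = (dxhat * self._xhat).sum(axis=axes, keepdims=True)
        return self._inv.reshape(shape) * (dxhat - t1 / m - self._xhat * t2 / m)


class MaxPool1d(Layer):
    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train):
        n, c, length = x.shape
        lo = length // self.size
        xt = x[:, :, : lo * self.size].reshape(n, c, lo, self.size)
        self._arg = xt.argmax(axis=3)
        self._shape = x.shape
        return xt.max(axis=3)

    def backward(self, dout):
        n, c, length = self._shape
        lo = dout.shape[2]
        dx = np.zeros((n, c, lo, self.size), dtype=dout.dtype)
        np.put_along_axis(dx, self._arg[..., None], dout[..., None], axis=3)
        out = np.zeros(self._shape, dtype=dout.dtype)
        out[:, :, : lo * self.size] = dx.reshape(n, c, lo * self.size)
        return out


class MaxPool2d(Layer):
    def __init__(self, size: int | tuple[int, int] = 2):
        self.sh, self.sw = (size, size) if isinstance(size, int) else size

    def forward(self, x, train):
        # two-stage max (width, then height) avoids transposed window copies
        n, c, hh, ww = x.shape
        ho, wo = hh // self.sh, ww // self.sw
        self._shape = x.shape
        a = x[:, :, : ho * self.sh, : wo * self.sw].reshape(n, c, ho * self.sh, wo, self.sw)
        self._argw = a.argmax(axis=4)
        mw = np.take_along_axis(a, self._argw[..., None], axis=4)[..., 0]
        b = mw.reshape(n, c, ho, self.sh, wo)
        self._argh = b.argmax(axis=3)
        return np.take_along_axis(b, self._argh[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout):
        n, c, hh, ww = self._shape
        ho, wo = dout.shape[2], dout.shape[3]
        db = np.zeros((n, c, ho, self.sh, wo), dtype=dout.dtype)
        np.put_along_axis(db, self._argh[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        da = np.zeros((n, c, ho * self.sh, wo, self.sw), dtype=dout.dtype)
        np.put_along_axis(da, self._argw[..., None], db.reshape(n, c, ho * self.sh, wo)[..., None], axis=4)
        out = np.zeros(self._shape, dtype=dout.dtype)
        out[:, :, : ho * self.sh, : wo * self.sw] = da.reshape(
            n, c, ho * self.sh, wo * self.sw
        )
        return out


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Residual(Layer):
    """y = ReLU(branch(x) + skip(x)); skip defaults to the identity.

    With all branch parameters at zero and an identity skip, the block is the
    identity map on non-negative inputs.
    """

    def __init__(self, branch: list[Layer], projection: list[Layer] | None = None):
        self.branch = branch
        self.projection = projection or []

    def params(self):
        out = []
        for layer in self.branch + self.projection:
            out.extend(layer.params())
        return out

    def forward(self, x, train):
        h = x
        for layer in self.branch:
            h = layer.forward(h, train)
        s = x
        for layer in self.projection:
            s = layer.forward(s, train)
        y = h + s
        self._mask = y > 0
        return y * self._mask

    def backward(self, dout):
        dy = dout * self._mask
        dh = dy
        for layer in reversed(self.branch):
            dh = layer.backward(dh)
        ds = dy
        for layer in reversed(self.projection):
            ds = layer.backward(ds)
        return dh + ds
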