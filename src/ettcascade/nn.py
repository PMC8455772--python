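"""Minimal CPU neural-network engine.

Implements exactly the primitives the backbone needs — 3x3 convolution
(stride 1 or 2, zero padding 1), batch normalization, LeakyReLU, global
average pooling / flattening, fully connected layers, Xavier-uniform
initialization and the Adam optimizer — as plain numpy with hand-written
backprop.  Convolutions run as im2col + BLAS matmul.  Tensors are NCHW.

Every layer's gradient is verified against finite differences in the test
suite; do not change backward passes without re-running those checks.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


def xavier_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int,
                   rng: np.random.Generator, dtype=np.float32) -> np.ndarray:
    limit = float(np.sqrt(6.0 / (fan_in + fan_out)))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _im2col(x: np.ndarray, stride: int) -> np.ndarray:
    """(N,C,H,W) -> (N, Ho, Wo, C*9) patches of a 3x3 kernel, pad 1."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    v = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    v = v[:, :, ::stride, ::stride]  # (n, c, ho, wo, 3, 3)
    ho, wo = v.shape[2], v.shape[3]
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(n, ho, wo, c * 9)


def _col2im(dcols: np.ndarray, x_shape: tuple[int, ...], stride: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patch gradients back."""
    n, c, h, w = x_shape
    ho, wo = dcols.shape[1], dcols.shape[2]
    d = dcols.reshape(n, ho, wo, c, 3, 3).transpose(0, 3, 1, 2, 4, 5)
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    for ki in range(3):
        for kj in range(3):
            dxp[:, :, ki:ki + stride * (ho - 1) + 1:stride,
                kj:kj + stride * (wo - 1) + 1:stride] += d[..., ki, kj]
    return dxp[:, :, 1:h + 1, 1:w + 1]


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """3x3 convolution, zero padding 1, stride 1 or 2, Xavier-uniform init."""

    def __init__(self, c_in: int, c_out: int, stride: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.c_in, self.c_out, self.stride = c_in, c_out, stride
        self.w = Param(xavier_uniform((c_out, c_in, 3, 3), c_in * 9, c_out * 9,
                                      rng, dtype), "conv.w")
        self.b = Param(np.zeros(c_out, dtype=dtype), "conv.b")
        self._cols: np.ndarray | None = None
        self._x_shape: tuple[int, ...] | None = None

    def forward(self, x, train=False):
        self._x_shape = x.shape
        cols = _im2col(x, self.stride)
        self._cols = cols if train else None
        n, ho, wo, _ = cols.shape
        wmat = self.w.value.reshape(self.c_out, -1)
        out = cols.reshape(-1, cols.shape[-1]) @ wmat.T
        out += self.b.value
        return np.ascontiguousarray(
            out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2))

    def backward(self, dy):
        assert self._cols is not None, "backward requires forward(train=True)"
        n, co, ho, wo = dy.shape
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, co)
        colsm = self._cols.reshape(-1, self._cols.shape[-1])
        self.w.grad += (dyf.T @ colsm).reshape(self.w.value.shape)
        self.b.grad += dyf.sum(axis=0)
        dcols = dyf @ self.w.value.reshape(co, -1)
        dcols = dcols.reshape(n, ho, wo, -1)
        self._cols = None
        return _col2im(dcols, self._x_shape, self.stride)

    def params(self):
        return [self.w, self.b]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32) -> None:
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(c, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(c, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self._cache = None

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        if train:
            self._cache = (xhat, ivar)
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, dy):
        assert self._cache is not None
        xhat, ivar = self._cache
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (ivar[None, :, None, None] / n) * (n * dxhat - s1 - xhat * s2)
        self._cache = None
        return dx.astype(dy.dtype)

    def params(self):
        return [self.gamma, self.beta]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.3) -> None:
        self.slope = slope
        self._mask = None

    def forward(self, x, train=False):
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, dy):
        dx = np.where(self._mask, dy, self.slope * dy)
        self._mask = None
        return dx


class GlobalAvgPool(Layer):
    def __init__(self) -> None:
        self._hw = None

    def forward(self, x, train=False):
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        h, w = self._hw
        return np.broadcast_to(dy[:, :, None, None] / (h * w),
                               dy.shape + (h, w)).astype(dy.dtype).copy()


class Flatten(Layer):
    def __init__(self) -> None:
        self._shape = None

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        rng = rng if rng is not None else np.random.default_rng(0)
        self.w = Param(xavier_uniform((d_out, d_in), d_in, d_out, rng, dtype), "fc.w")
        self.b = Param(np.zeros(d_out, dtype=dtype), "fc.b")
        self._x = None

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.w.value
        self._x = None
        return dx

    def params(self):
        return [self.w, self.b]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


class Adam:
    """Adam with bias correction (eps follows the TF default of 1e-7)."""

    def __init__(self, params: list[Param], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1 - self.beta1 ** self.t
        b2c = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * np.square(p.grad)
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
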