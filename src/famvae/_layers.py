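"""Minimal neural-network primitives (forward + backprop) in numpy.

Everything the sequence VAE needs: 3x3 same-padding 2D convolution (via
im2col), batch normalization, ELU, 2x max pooling and nearest-neighbor
upsampling along the length dimension only, dense layers, and Adam.
Tensors are channels-last: (batch, length, alphabet, channels).

Gradient correctness is pinned by finite-difference checks in the test
suite; keep any change to a backward pass covered there.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "BatchNorm",
    "ELU",
    "MaxPoolLen",
    "UpsampleLen",
    "Dense",
    "Adam",
    "kaiming_normal",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("val", "grad")

    def __init__(self, val: np.ndarray):
        self.val = val
        self.grad = np.zeros_like(val)


def kaiming_normal(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, dtype) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class Layer:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        return {}

    def set_buffers(self, bufs: dict[str, np.ndarray]) -> None:
        pass

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (configurable) convolution with same padding, channels-last.

    Computed as k*k shifted matrix products against the (k, k, c_in, c_out)
    kernel — no im2col buffer, so memory stays at one padded copy of the
    input.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, dtype=np.float32):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k = kernel
        self.c_in = c_in
        self.c_out = c_out
        fan_in = kernel * kernel * c_in
        self.W = Param(
            kaiming_normal(rng, (kernel, kernel, c_in, c_out), fan_in, dtype)
        )
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        k, p = self.k, self.k // 2
        B, H, Wd, C = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.empty((B, H, Wd, self.c_out), dtype=x.dtype)
        out[...] = self.b.val
        for ki in range(k):
            for kj in range(k):
                patch = xp[:, ki:ki + H, kj:kj + Wd, :].reshape(-1, C)
                out += (patch @ self.W.val[ki, kj]).reshape(B, H, Wd, self.c_out)
        if train:
            self._xp = xp
            self._in_shape = x.shape
        return out

    def backward(self, dout):
        k, p = self.k, self.k // 2
        B, H, Wd, C = self._in_shape
        xp = self._xp
        dflat = dout.reshape(-1, self.c_out)
        self.b.grad += dflat.sum(axis=0)
        dxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                patch = xp[:, ki:ki + H, kj:kj + Wd, :].reshape(-1, C)
                self.W.grad[ki, kj] += patch.T @ dflat
                dxp[:, ki:ki + H, kj:kj + Wd, :] += (
                    dflat @ self.W.val[ki, kj].T
                ).reshape(B, H, Wd, C)
        self._xp = None
        return dxp[:, p:p + H, p:p + Wd, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, length, alphabet)."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def set_buffers(self, bufs):
        self.running_mean = bufs["running_mean"]
        self.running_var = bufs["running_var"]

    def forward(self, x, train):
        axes = (0, 1, 2)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._xhat = xhat
            self._inv_std = inv_std
            self._n = x.shape[0] * x.shape[1] * x.shape[2]
        return self.gamma.val * xhat + self.beta.val

    def backward(self, dout):
        axes = (0, 1, 2)
        xhat, inv_std, n = self._xhat, self._inv_std, self._n
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.val
        dx = (inv_std / n) * (
            n * dxhat
            - dxhat.sum(axis=axes)
            - xhat * (dxhat * xhat).sum(axis=axes)
        )
        self._xhat = None
        return dx


class ELU(Layer):
    def forward(self, x, train):
        out = np.where(x > 0, x, np.expm1(x))
        if train:
            self._x = x
            self._out = out
        return out

    def backward(self, dout):
        dx = dout * np.where(self._x > 0, 1.0, self._out + 1.0)
        self._x = self._out = None
        return dx


class MaxPoolLen(Layer):
    """2x max pooling along the length axis only."""

    def forward(self, x, train):
        B, H, Wd, C = x.shape
        if H % 2:
            raise ValueError("length must be even for 2x pooling")
        xr = x.reshape(B, H // 2, 2, Wd, C)
        idx = xr.argmax(axis=2)
        out = np.take_along_axis(xr, idx[:, :, None, :, :], axis=2)[:, :, 0]
        if train:
            self._idx = idx
            self._shape = x.shape
        return out

    def backward(self, dout):
        B, H, Wd, C = self._shape
        dxr = np.zeros((B, H // 2, 2, Wd, C), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[:, :, None, :, :],
                          dout[:, :, None, :, :], axis=2)
        self._idx = None
        return dxr.reshape(B, H, Wd, C)


class UpsampleLen(Layer):
    """2x nearest-neighbor upsampling along the length axis only."""

    def forward(self, x, train):
        if train:
            self._shape = x.shape
        return np.repeat(x, 2, axis=1)

    def backward(self, dout):
        B, H, Wd, C = self._shape
        return dout.reshape(B, H, 2, Wd, C).sum(axis=2)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.W = Param(kaiming_normal(rng, (n_in, n_out), n_in, dtype))
        self.b = Param(np.zeros(n_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W.val + self.b.val

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        dx = dout @ self.W.val.T
        self._x = None
        return dx


class Adam:
    """Adam optimizer over a flat list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.val) for p in params]
        self.v = [np.zeros_like(p.val) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.val -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
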