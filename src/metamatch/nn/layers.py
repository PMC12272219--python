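"""Differentiable layers: 3D convolution, batch norm, max pooling, ReLU,
dropout, global average pooling and a dense output map.

Convolution is stride-1 with size-preserving (zero) padding, computed as a
single im2col matrix product per layer. Compute dtype is configurable
(float32 by default; float64 for high-precision checks).
"""

from __future__ import annotations

import numpy as np

from ._kernels import (bn_apply, bn_bwd, bn_fwd_stats, col2im_3d, im2col_3d,
                       maxpool3d_bwd, maxpool3d_fwd)


class Layer:
    """Base: parameterized layers keep ``params`` and matching ``grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """Stride-1 'same' 3D convolution, channels-last, He-normal init."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32,
                 input_grad: bool = True) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd for size-preserving padding")
        self.k = kernel_size
        self.cin = in_channels
        self.cout = out_channels
        self.input_grad = input_grad  # the first layer's input needs no gradient
        self.dtype = np.dtype(dtype)
        fan_in = in_channels * kernel_size ** 3
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      size=(kernel_size,) * 3 + (in_channels, out_channels)
                                      ).astype(self.dtype)
        self.params["b"] = np.zeros(out_channels, dtype=self.dtype)

    def forward(self, x, training=False, rng=None):
        n, D, H, Wd, c = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        p = self.k // 2
        x = np.ascontiguousarray(x)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0))) if p else x
        nvox = n * D * H * Wd
        xcol = np.empty((nvox, self.k ** 3 * self.cin), dtype=x.dtype)
        im2col_3d(xp, self.k, D, H, Wd, xcol)
        self._xcol = xcol if training else None
        self._shape = (n, D, H, Wd)
        W2d = self.params["W"].reshape(-1, self.cout)
        out2d = xcol @ W2d + self.params["b"]
        return out2d.reshape(n, D, H, Wd, self.cout)

    def backward(self, grad):
        n, D, H, Wd = self._shape
        if self._xcol is None:
            raise RuntimeError("backward requires a training-mode forward")
        g2d = np.ascontiguousarray(grad).reshape(-1, self.cout)
        W2d = self.params["W"].reshape(-1, self.cout)
        self.grads["W"] = (self._xcol.T @ g2d).reshape(self.params["W"].shape)
        self.grads["b"] = g2d.sum(axis=0)
        self._xcol = None
        if not self.input_grad:
            return None
        dxcol = np.ascontiguousarray(g2d @ W2d.T)
        p = self.k // 2
        dxp = np.zeros((n, D + 2 * p, H + 2 * p, Wd + 2 * p, self.cin),
                       dtype=grad.dtype)
        col2im_3d(dxcol, self.k, D, H, Wd, dxp)
        if p:
            return dxp[:, p:-p, p:-p, p:-p, :]
        return dxp


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics for eval mode."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        dtype = np.dtype(dtype)
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x, training=False, rng=None):
        shape = x.shape
        C = shape[-1]
        x2d = np.ascontiguousarray(x).reshape(-1, C)
        if training:
            mu64, var64 = bn_fwd_stats(x2d)
            mu = mu64.astype(x2d.dtype)
            var = var64.astype(x2d.dtype)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(mu.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(var.dtype)
        else:
            mu = self.running_mean.astype(x2d.dtype)
            var = self.running_var.astype(x2d.dtype)
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x2d.dtype)
        xhat = np.empty_like(x2d)
        out = np.empty_like(x2d)
        bn_apply(x2d, mu, inv, self.params["gamma"].astype(x2d.dtype),
                 self.params["beta"].astype(x2d.dtype), xhat, out)
        self._xhat, self._inv, self._shape = xhat, inv, shape
        self._training = training
        return out.reshape(shape)

    def backward(self, grad):
        C = self._shape[-1]
        g2d = np.ascontiguousarray(grad).reshape(-1, C)
        dgamma = np.zeros(C, dtype=g2d.dtype)
        dbeta = np.zeros(C, dtype=g2d.dtype)
        out = np.empty_like(g2d)
        ginv = (self.params["gamma"].astype(g2d.dtype)
                * self._inv.astype(g2d.dtype))
        bn_bwd(g2d, self._xhat, ginv, dgamma, dbeta, out, self._training)
        self.grads["gamma"] = dgamma.astype(self.params["gamma"].dtype)
        self.grads["beta"] = dbeta.astype(self.params["beta"].dtype)
        return out.reshape(self._shape)


class MaxPool3d(Layer):
    """2×2×2 max pooling with stride 2; odd trailing voxels are dropped.

    Gradient routes to the first maximum within each window (deterministic
    tie-break).
    """

    def forward(self, x, training=False, rng=None):
        n, D, H, Wd, C = x.shape
        d2, h2, w2 = D // 2, H // 2, Wd // 2
        if min(d2, h2, w2) < 1:
            raise ValueError(f"spatial extent {x.shape[1:4]} too small to pool")
        x = np.ascontiguousarray(x)
        out = np.empty((n, d2, h2, w2, C), dtype=x.dtype)
        idx = np.empty((n, d2, h2, w2, C), dtype=np.uint8)
        maxpool3d_fwd(x, out, idx)
        self._idx = idx
        self._in_shape = x.shape
        return out

    def backward(self, grad):
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        maxpool3d_bwd(np.ascontiguousarray(grad), self._idx, dx)
        return dx


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = ((rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
                      ).astype(x.dtype)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class GlobalAvgPool(Layer):
    """Average over all spatial axes: (n, X, Y, Z, C) → (n, C)."""

    def forward(self, x, training=False, rng=None):
        self._in_shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, grad):
        n, D, H, Wd, C = self._in_shape
        scale = 1.0 / (D * H * Wd)
        return np.broadcast_to(grad[:, None, None, None, :] * scale, self._in_shape).copy()


class Linear(Layer):
    """Dense map (n, F) → (n, P); equivalent to a 1×1×1 convolution on pooled features."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 init_std: float | None = None, dtype=np.float32) -> None:
        super().__init__()
        dtype = np.dtype(dtype)
        std = init_std if init_std is not None else np.sqrt(2.0 / in_features)
        self.params["W"] = rng.normal(0.0, std, size=(in_features, out_features)).astype(dtype)
        self.params["b"] = np.zeros(out_features, dtype=dtype)

    def forward(self, x, training=False, rng=None):
        if x.shape[1] != self.params["W"].shape[0]:
            raise ValueError(f"expected {self.params['W'].shape[0]} features, got {x.shape[1]}")
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T
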