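"""Convolutional / normalization / pooling layers with manual backprop.

Temporal convolutions (kernel ``(K, 1)`` over a channels-last ``(B, T, S, C)``
map) are computed in the frequency domain: one rFFT of the padded input serves
the forward pass and, cached, both gradient passes — the forward is a
cross-correlation, the input gradient a full convolution, and the weight
gradient another cross-correlation, all diagonal in Fourier space.  This keeps
kernels of length 500 on 1000-sample windows cheap without any framework.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

from .core import Module, Parameter, ShapeError

__all__ = [
    "TemporalConv",
    "DepthwiseSpatialConv",
    "BatchNorm",
    "ELU",
    "ReLU",
    "Dropout",
    "AvgPoolTime",
    "Flatten",
    "Dense",
    "LayerNorm",
    "Tokenize",
    "Untokenize",
    "ECA",
    "glorot_uniform",
]


def glorot_uniform(
    rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int,
    dtype=np.float64,
) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class TemporalConv(Module):
    """2-D convolution with kernel ``(K, 1)``, stride 1, 'same' padding, bias.

    'Same' padding follows the usual convention: ``K - 1`` zeros in total,
    ``(K - 1) // 2`` on the left, the remainder on the right, so the output
    temporal length equals the input length for odd and even kernels alike.
    """

    def __init__(
        self,
        kernel_len: int,
        in_channels: int,
        filters: int,
        rng: np.random.Generator,
        dtype=np.float64,
    ):
        super().__init__()
        if kernel_len < 1 or filters < 1:
            raise ValueError("kernel_len and filters must be >= 1")
        self.kernel_len = kernel_len
        self.in_channels = in_channels
        self.filters = filters
        fan_in = kernel_len * in_channels
        fan_out = kernel_len * filters
        self.W = Parameter(
            glorot_uniform(rng, (kernel_len, in_channels, filters), fan_in, fan_out, dtype),
            "conv.W",
        )
        self.b = Parameter(np.zeros(filters, dtype=dtype), "conv.b")
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, S, C = x.shape
        if C != self.in_channels:
            raise ShapeError(
                f"TemporalConv(K={self.kernel_len}) expects {self.in_channels} "
                f"input channels, got {C}"
            )
        K = self.kernel_len
        pad_left = (K - 1) // 2
        pad_right = K - 1 - pad_left
        Tp = T + K - 1
        n = next_fast_len(Tp)
        xp = np.pad(x, ((0, 0), (pad_left, pad_right), (0, 0), (0, 0)))
        Xf = rfft(xp, n, axis=1)
        Wf = rfft(self.W.value.astype(x.dtype, copy=False), n, axis=0)
        # forward = cross-correlation: Y = irfft(X * conj(W))
        Yf = np.einsum("bfsc,fco->bfso", Xf, Wf.conj())
        y = irfft(Yf, n, axis=1)[:, :T]
        self._cache = (Xf, Wf, T, Tp, n, pad_left)
        return (y + self.b.value).astype(x.dtype)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        Xf, Wf, T, Tp, n, pad_left = self._cache
        K = self.kernel_len
        dYf = rfft(grad, n, axis=1)
        # dW = cross-correlation of padded input with the output gradient
        dWf = np.einsum("bfsc,bfso->fco", Xf, dYf.conj())
        dW = irfft(dWf, n, axis=0)[:K]
        self.W.grad += dW.astype(self.W.value.dtype)
        self.b.grad += grad.sum(axis=(0, 1, 2)).astype(self.b.value.dtype)
        # dX = full convolution of the output gradient with the kernel
        dXf = np.einsum("bfso,fco->bfsc", dYf, Wf)
        dxp = irfft(dXf, n, axis=1)[:, :Tp]
        return np.ascontiguousarray(dxp[:, pad_left : pad_left + T]).astype(
            grad.dtype
        )


class DepthwiseSpatialConv(Module):
    """Depthwise conv with kernel ``(1, S)`` and a depth multiplier, no bias.

    Acts as a learned spatial filter across electrodes: the spatial axis
    collapses from S to 1 and each input channel spawns ``depth`` outputs.
    """

    def __init__(
        self,
        spatial: int,
        in_channels: int,
        depth: int,
        rng: np.random.Generator,
        dtype=np.float64,
    ):
        super().__init__()
        self.spatial = spatial
        self.in_channels = in_channels
        self.depth = depth
        fan_in = spatial
        fan_out = spatial * depth
        self.W = Parameter(
            glorot_uniform(rng, (spatial, in_channels, depth), fan_in, fan_out, dtype),
            "dwconv.W",
        )
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, S, C = x.shape
        if S != self.spatial or C != self.in_channels:
            raise ShapeError(
                f"DepthwiseSpatialConv expects (.., {self.spatial}, "
                f"{self.in_channels}); got (.., {S}, {C})"
            )
        self._x = x
        y = np.einsum("btsc,scm->btcm", x, self.W.value)
        return y.reshape(B, T, 1, C * self.depth)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, S, C = x.shape
        g = grad.reshape(B, T, C, self.depth)
        self.W.grad += np.einsum("btsc,btcm->scm", x, g)
        return np.einsum("btcm,scm->btsc", g, self.W.value)


class BatchNorm(Module):
    """Batch normalization over the channel axis with moving statistics.

    Contributes 4 parameters per channel to the model's parameter count
    (scale, shift, moving mean, moving variance) as frameworks report it.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3,
                 dtype=np.float64):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=dtype), "bn.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=dtype), "bn.beta")
        self.moving_mean = np.zeros(channels, dtype=dtype)
        self.moving_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def own_buffers(self) -> list[np.ndarray]:
        return [self.moving_mean, self.moving_var]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            xc = x - mean
            xc2 = xc.reshape(-1, x.shape[-1])
            var = np.einsum("nc,nc->c", xc2, xc2) / xc2.shape[0]
            self.moving_mean[...] = (
                self.momentum * self.moving_mean + (1 - self.momentum) * mean
            )
            self.moving_var[...] = (
                self.momentum * self.moving_var + (1 - self.momentum) * var
            )
            inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
            xhat = xc * inv
            self._cache = (xhat, inv, axes, x.shape)
        else:
            mean, var = self.moving_mean, self.moving_var
            inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
            xhat = (x - mean.astype(x.dtype)) * inv
        return (self.gamma.value.astype(x.dtype) * xhat
                + self.beta.value.astype(x.dtype))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, axes, shape = self._cache
        n = np.prod([shape[a] for a in axes])
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value
        return inv * (
            g - g.mean(axis=axes) - xhat * (g * xhat).mean(axis=axes)
        ) if n > 1 else g * inv


class ELU(Module):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        neg = x < 0
        y = np.where(neg, self.alpha * np.expm1(np.minimum(x, 0.0)), x)
        self._cache = (neg, y)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        neg, y = self._cache
        return grad * np.where(neg, y + self.alpha, 1.0)


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Dropout(Module):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1); got {rate}")
        self.rate = rate
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = 1.0
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class AvgPoolTime(Module):
    """Average pooling ``(p, 1)`` over the temporal axis; requires T % p == 0."""

    def __init__(self, pool: int):
        super().__init__()
        if pool < 1:
            raise ValueError(f"pool size must be >= 1; got {pool}")
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, S, C = x.shape
        if T % self.pool:
            raise ShapeError(
                f"AvgPool({self.pool}, 1): temporal length {T} not divisible"
            )
        self._T = T
        return x.reshape(B, T // self.pool, self.pool, S, C).mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, t, S, C = grad.shape
        g = np.broadcast_to(
            grad[:, :, None] / self.pool, (B, t, self.pool, S, C)
        )
        return g.reshape(B, self._T, S, C)


class Flatten(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        super().__init__()
        self.W = Parameter(
            glorot_uniform(rng, (d_in, d_out), d_in, d_out, dtype), "dense.W"
        )
        self.b = Parameter(np.zeros(d_out, dtype=dtype), "dense.b")
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.W.value.shape[0]:
            raise ShapeError(
                f"Dense expects last dim {self.W.value.shape[0]}, got {x.shape[-1]}"
            )
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = grad.reshape(-1, grad.shape[-1])
        self.W.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return grad @ self.W.value.T


class LayerNorm(Module):
    """Normalization over the last axis with learned scale and shift."""

    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float64):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=dtype), "ln.gamma")
        self.beta = Parameter(np.zeros(dim, dtype=dtype), "ln.beta")
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=tuple(range(grad.ndim - 1)))
        self.beta.grad += grad.sum(axis=tuple(range(grad.ndim - 1)))
        g = grad * self.gamma.value
        return inv * (
            g
            - g.mean(axis=-1, keepdims=True)
            - xhat * (g * xhat).mean(axis=-1, keepdims=True)
        )


class Tokenize(Module):
    """Reshape a ``(B, T, 1, C)`` feature map to ``(B, C, T)`` token matrix.

    Tokens are the feature channels; token width is the temporal axis."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, S, C = x.shape
        if S != 1:
            raise ShapeError(f"Tokenize expects a collapsed spatial axis; got S={S}")
        return np.ascontiguousarray(x[:, :, 0, :].transpose(0, 2, 1))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(grad.transpose(0, 2, 1))[:, :, None, :]


class Untokenize(Module):
    """Inverse of :class:`Tokenize`: ``(B, C, T)`` back to ``(B, T, 1, C)``."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.ascontiguousarray(x.transpose(0, 2, 1))[:, :, None, :]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(grad[:, :, 0, :].transpose(0, 2, 1))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class ECA(Module):
    """Efficient channel attention: per-channel gates in (0, 1).

    Global average pooling produces a channel descriptor; a 1-D convolution of
    kernel size k (odd, adaptively chosen from the channel count) across the
    descriptor followed by a sigmoid yields the gates that rescale the
    channels.  Carries ``k`` weights plus one bias.
    """

    def __init__(self, channels: int, k: int, rng: np.random.Generator,
                 dtype=np.float64):
        super().__init__()
        if k < 1 or k % 2 == 0:
            raise ValueError(f"ECA kernel size must be a positive odd integer; got {k}")
        self.channels = channels
        self.k = k
        self.W = Parameter(glorot_uniform(rng, (k,), k, k, dtype), "eca.W")
        self.b = Parameter(np.zeros(1, dtype=dtype), "eca.b")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, S, C = x.shape
        g = x.mean(axis=(1, 2))  # (B, C) channel descriptor
        half = self.k // 2
        gp = np.pad(g, ((0, 0), (half, half)))
        z = np.zeros_like(g) + self.b.value
        for j in range(self.k):
            z += self.W.value[j] * gp[:, j : j + C]
        a = _sigmoid(z)
        self._cache = (x, g, gp, a)
        return x * a[:, None, None, :]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, g, gp, a = self._cache
        B, T, S, C = x.shape
        half = self.k // 2
        dx = grad * a[:, None, None, :]
        da = (grad * x).sum(axis=(1, 2))
        dz = da * a * (1.0 - a)
        self.b.grad += dz.sum()
        dgp = np.zeros_like(gp)
        for j in range(self.k):
            self.W.grad[j] += (dz * gp[:, j : j + C]).sum()
            dgp[:, j : j + C] += self.W.value[j] * dz
        dg = dgp[:, half : half + C]
        dx += dg[:, None, None, :] / (T * S)
        return dx
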