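"""Multi-head self-attention and feed-forward sub-layers with backprop.

The encoder layer is the post-norm Transformer variant: each sub-layer output
is ``LayerNorm(x + SubLayer(x))``.  No positional encoding is used, so the
whole encoder commutes with token permutations — a property the test suite
exploits.
"""

from __future__ import annotations

import numpy as np

from .core import Module, Parameter, Sequential, ShapeError
from .layers import Dense, Dropout, LayerNorm, ReLU, glorot_uniform

__all__ = [
    "softmax",
    "MultiHeadAttention",
    "FeedForward",
    "Residual",
    "EncoderLayer",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadAttention(Module):
    """Scaled dot-product attention over h heads with biased projections.

    Input/output shape ``(B, tokens, d_model)``; per-head width
    ``d_k = d_model / h``; attention weights optionally dropped out in
    training.
    """

    def __init__(
        self,
        d_model: int,
        heads: int,
        rng: np.random.Generator,
        dropout: float = 0.0,
        dtype=np.float64,
    ):
        super().__init__()
        if d_model % heads:
            raise ValueError(f"d_model={d_model} not divisible by heads={heads}")
        self.d_model = d_model
        self.heads = heads
        self.d_k = d_model // heads
        def proj(name):
            return Parameter(
                glorot_uniform(rng, (d_model, d_model), d_model, d_model, dtype),
                name,
            )
        self.Wq, self.Wk, self.Wv, self.Wo = (
            proj("mha.Wq"), proj("mha.Wk"), proj("mha.Wv"), proj("mha.Wo")
        )
        self.bq = Parameter(np.zeros(d_model, dtype=dtype), "mha.bq")
        self.bk = Parameter(np.zeros(d_model, dtype=dtype), "mha.bk")
        self.bv = Parameter(np.zeros(d_model, dtype=dtype), "mha.bv")
        self.bo = Parameter(np.zeros(d_model, dtype=dtype), "mha.bo")
        self.attn_dropout = Dropout(dropout)

    def _split(self, m: np.ndarray) -> np.ndarray:
        B, N, D = m.shape
        return m.reshape(B, N, self.heads, self.d_k).transpose(0, 2, 1, 3)

    def _merge(self, m: np.ndarray) -> np.ndarray:
        B, h, N, dk = m.shape
        return np.ascontiguousarray(m.transpose(0, 2, 1, 3)).reshape(B, N, h * dk)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 3 or x.shape[-1] != self.d_model:
            raise ShapeError(
                f"MultiHeadAttention expects (B, tokens, {self.d_model}); "
                f"got {x.shape}"
            )
        Q = self._split(x @ self.Wq.value + self.bq.value)
        K = self._split(x @ self.Wk.value + self.bk.value)
        V = self._split(x @ self.Wv.value + self.bv.value)
        scale = 1.0 / np.sqrt(self.d_k)
        logits = (Q @ K.transpose(0, 1, 3, 2)) * scale
        A = softmax(logits, axis=-1)
        Ad = self.attn_dropout.forward(A, train=train)
        ctx = self._merge(Ad @ V)
        y = ctx @ self.Wo.value + self.bo.value
        self._cache = (x, Q, K, V, A, Ad, ctx, scale)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, Q, K, V, A, Ad, ctx, scale = self._cache
        B, N, D = x.shape
        g2 = grad.reshape(-1, D)
        self.Wo.grad += ctx.reshape(-1, D).T @ g2
        self.bo.grad += g2.sum(axis=0)
        dctx = self._split(grad @ self.Wo.value.T)
        dAd = dctx @ V.transpose(0, 1, 3, 2)
        dV = Ad.transpose(0, 1, 3, 2) @ dctx
        dA = self.attn_dropout.backward(dAd)
        dlogits = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dlogits *= scale
        dQ = dlogits @ K
        dK = dlogits.transpose(0, 1, 3, 2) @ Q
        x2 = x.reshape(-1, D)
        dx = np.zeros_like(x)
        for dM, W, b in ((dQ, self.Wq, self.bq), (dK, self.Wk, self.bk),
                         (dV, self.Wv, self.bv)):
            dMm = self._merge(dM)
            d2 = dMm.reshape(-1, D)
            W.grad += x2.T @ d2
            b.grad += d2.sum(axis=0)
            dx += dMm @ W.value.T
        return dx


class FeedForward(Module):
    """Position-wise ReLU MLP: ``max(0, z W1 + b1) W2 + b2``."""

    def __init__(
        self,
        d_model: int,
        d_ff: int,
        rng: np.random.Generator,
        dropout: float = 0.0,
        dtype=np.float64,
    ):
        super().__init__()
        self.net = Sequential([
            Dense(d_model, d_ff, rng, dtype),
            ReLU(),
            Dropout(dropout),
            Dense(d_ff, d_model, rng, dtype),
        ])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train=train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)


class Residual(Module):
    """``x + sublayer(x)``."""

    def __init__(self, sublayer: Module):
        super().__init__()
        self.sublayer = sublayer

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x + self.sublayer.forward(x, train=train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad + self.sublayer.backward(grad)


def EncoderLayer(
    d_model: int,
    heads: int,
    d_ff: int,
    rng: np.random.Generator,
    dropout: float = 0.0,
    dtype=np.float64,
) -> Sequential:
    """One post-norm encoder layer: MHA and FFN sub-layers, each wrapped in
    residual-add followed by layer normalization."""
    return Sequential([
        Residual(MultiHeadAttention(d_model, heads, rng, dropout, dtype)),
        LayerNorm(d_model, dtype=dtype),
        Residual(FeedForward(d_model, d_ff, rng, dropout, dtype)),
        LayerNorm(d_model, dtype=dtype),
    ])
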