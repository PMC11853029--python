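"""Transformer-style encoder: configuration and reference forward math.

The MSEI output ``(125, 1, 72)`` is read as 72 tokens of width 125 (tokens =
feature channels, token width = temporal samples).  The encoder stacks two
identical post-norm layers — multi-head scaled-dot-product self-attention and
a position-wise ReLU feed-forward network, each wrapped in residual-add +
layer normalization.  No positional encoding is used.

This module exposes the math as plain functions on explicit parameter
dictionaries (useful for oracles and inspection); the trainable layers in
:mod:`mseienet.nn.attention` implement the same computation with backprop and
are cross-checked against these functions in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.attention import softmax

__all__ = [
    "EncoderConfig",
    "project_qkv",
    "scaled_dot_attention",
    "multi_head_attention",
    "feed_forward",
    "encoder_forward",
    "build_encoder",
    "encoder_parameter_count",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Encoder hyperparameters.

    ``d_ff`` defaults to 435, the integer feed-forward width whose total
    parameter count comes closest to the reference architecture's printed
    encoder size under standard layer conventions (all projections biased).
    """

    tokens: int = 72
    d_model: int = 125
    heads: int = 5
    n_layers: int = 2
    d_ff: int = 435
    dropout: float = 0.3

    def __post_init__(self) -> None:
        if self.d_model % self.heads:
            raise ValueError(
                f"d_model={self.d_model} must be divisible by heads={self.heads}"
            )
        if self.d_ff < 1 or self.n_layers < 1:
            raise ValueError("d_ff and n_layers must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError(f"dropout must be in [0, 1); got {self.dropout}")

    @property
    def d_k(self) -> int:
        """Per-head width."""
        return self.d_model // self.heads


def project_qkv(
    E: np.ndarray,
    Wq: np.ndarray, Wk: np.ndarray, Wv: np.ndarray,
    bq: np.ndarray | float = 0.0, bk: np.ndarray | float = 0.0,
    bv: np.ndarray | float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear projections ``Q = E Wq + bq`` etc. for a tokens x d_model input."""
    for name, W in (("Wq", Wq), ("Wk", Wk), ("Wv", Wv)):
        if E.shape[-1] != W.shape[0]:
            raise nn.ShapeError(
                f"{name} has {W.shape[0]} rows for input width {E.shape[-1]}"
            )
    return E @ Wq + bq, E @ Wk + bk, E @ Wv + bv


def scaled_dot_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, d_k: int
) -> tuple[np.ndarray, np.ndarray]:
    """``softmax(Q K^T / sqrt(d_k)) V``; returns (output, attention weights).

    Every attention row sums to 1.
    """
    if d_k <= 0:
        raise ValueError(f"d_k must be positive; got {d_k}")
    logits = Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k)
    weights = softmax(logits, axis=-1)
    return weights @ V, weights


def multi_head_attention(E: np.ndarray, params: dict, heads: int) -> np.ndarray:
    """Multi-head attention on a ``(tokens, d_model)`` (or batched) input.

    ``params`` holds ``Wq, Wk, Wv, Wo`` (d_model x d_model) and biases
    ``bq, bk, bv, bo``.  The projections are split into ``heads`` slices of
    width ``d_model / heads``, attended independently, concatenated and
    projected by ``Wo``.
    """
    d_model = E.shape[-1]
    if d_model % heads:
        raise ValueError(f"d_model={d_model} not divisible by heads={heads}")
    d_k = d_model // heads
    Q, K, V = project_qkv(
        E, params["Wq"], params["Wk"], params["Wv"],
        params.get("bq", 0.0), params.get("bk", 0.0), params.get("bv", 0.0),
    )
    outs = []
    for h in range(heads):
        sl = slice(h * d_k, (h + 1) * d_k)
        out, _ = scaled_dot_attention(Q[..., sl], K[..., sl], V[..., sl], d_k)
        outs.append(out)
    concat = np.concatenate(outs, axis=-1)
    return concat @ params["Wo"] + params.get("bo", 0.0)


def feed_forward(
    z: np.ndarray, W1: np.ndarray, b1: np.ndarray, W2: np.ndarray, b2: np.ndarray
) -> np.ndarray:
    """Position-wise MLP ``max(0, z W1 + b1) W2 + b2`` applied per token."""
    if z.shape[-1] != W1.shape[0] or W1.shape[1] != W2.shape[0]:
        raise nn.ShapeError(
            f"feed_forward shapes incompatible: z{z.shape}, W1{W1.shape}, "
            f"W2{W2.shape}"
        )
    return np.maximum(z @ W1 + b1, 0.0) @ W2 + b2


def _layer_norm(x: np.ndarray, gamma, beta, eps: float = 1e-5) -> np.ndarray:
    mean = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return gamma * (x - mean) / np.sqrt(var + eps) + beta


def encoder_forward(E: np.ndarray, config: EncoderConfig, params: list[dict]) -> np.ndarray:
    """Reference (inference-mode) forward pass through ``n_layers`` layers.

    ``params`` is one dict per layer with keys ``mha`` (projection params),
    ``ffn`` (``W1 b1 W2 b2``) and the layer-norm pairs ``ln1 ln2`` (each a
    ``(gamma, beta)`` tuple).  Each layer computes
    ``x <- LN(x + MHA(x)); x <- LN(x + FFN(x))``.
    """
    if E.ndim == 3 and E.shape[-1] != config.d_model and E.shape[-3] == config.d_model:
        raise nn.ShapeError(
            f"encoder input looks like an untokenized feature map {E.shape}; "
            f"expected (tokens, {config.d_model})"
        )
    x = E
    for layer in params[: config.n_layers]:
        g1, b1 = layer["ln1"]
        g2, b2 = layer["ln2"]
        x = _layer_norm(x + multi_head_attention(x, layer["mha"], config.heads), g1, b1)
        x = _layer_norm(x + feed_forward(x, *layer["ffn"]), g2, b2)
    return x


def build_encoder(
    config: EncoderConfig, rng: np.random.Generator, dtype=np.float64
) -> nn.Sequential:
    """Trainable encoder stack matching :func:`encoder_forward`."""
    return nn.Sequential([
        nn.EncoderLayer(
            config.d_model, config.heads, config.d_ff, rng, config.dropout, dtype
        )
        for _ in range(config.n_layers)
    ])


def encoder_parameter_count(config: EncoderConfig) -> int:
    """Closed-form parameter count of the encoder stack.

    Per layer: 4 biased d_model x d_model projections, the two-layer FFN, and
    two layer norms of 2 * d_model parameters each.
    """
    d, f = config.d_model, config.d_ff
    mha = 4 * (d * d + d)
    ffn = (d * f + f) + (f * d + d)
    ln = 2 * (2 * d)
    return config.n_layers * (mha + ffn + ln)
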