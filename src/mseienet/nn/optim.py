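"""Adam optimizer and the softmax cross-entropy loss."""

from __future__ import annotations

import numpy as np

from .core import Parameter

__all__ = ["Adam", "softmax_cross_entropy"]


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ):
        if lr < 0:
            raise ValueError(f"learning rate must be >= 0; got {lr}")
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy of softmax(logits) against integer labels.

    Returns ``(loss, dlogits, probs)`` with ``dlogits`` already averaged over
    the batch.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    idx = np.arange(n)
    loss = float(-np.log(np.maximum(probs[idx, labels], 1e-300)).mean())
    dlogits = probs.copy()
    dlogits[idx, labels] -= 1.0
    dlogits /= n
    return loss, dlogits, probs
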