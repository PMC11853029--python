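"""Minimal trainable-module substrate: parameters, modules, composition.

Every layer is a :class:`Module` with an explicit ``forward`` (caching what
its ``backward`` needs) and a ``backward`` returning the gradient w.r.t. its
input while accumulating parameter gradients.  Composition is by
:class:`Sequential` (chain) and :class:`Parallel` (same input to every branch,
outputs concatenated on the feature axis) — enough to express inception-style
convolution stacks and a Transformer encoder.

Conventions: feature maps are channels-last ``(batch, time, space, channels)``;
token matrices are ``(batch, tokens, d_model)``.  Parameter counting follows
the usual framework convention of including batch-norm moving statistics
(kept as non-trainable buffers), so ``count_parameters`` = trainable + buffers.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

__all__ = ["Parameter", "Module", "Sequential", "Parallel", "ShapeError"]


class ShapeError(ValueError):
    """An input's shape is incompatible with a layer."""


class Parameter:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Module:
    """Base class: a differentiable operation with parameters and buffers."""

    def __init__(self) -> None:
        self.rng: np.random.Generator = np.random.default_rng(0)

    # -- structure ---------------------------------------------------------
    def children(self) -> Iterator["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def modules(self) -> Iterator["Module"]:
        seen: set[int] = set()

        def walk(m: "Module") -> Iterator["Module"]:
            if id(m) in seen:
                return
            seen.add(id(m))
            yield m
            for child in m.children():
                yield from walk(child)

        yield from walk(self)

    def own_parameters(self) -> list[Parameter]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, (list, tuple)):
                out.extend(p for p in v if isinstance(p, Parameter))
        return out

    def parameters(self) -> list[Parameter]:
        out = []
        for m in self.modules():
            out.extend(m.own_parameters())
        return out

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. batch-norm moving statistics)."""
        out = []
        for m in self.modules():
            out.extend(m.own_buffers())
        return out

    def own_buffers(self) -> list[np.ndarray]:
        return []

    def count_parameters(self) -> int:
        """Total parameter count, moving statistics included."""
        return sum(p.size for p in self.parameters()) + sum(
            b.size for b in self.buffers()
        )

    def set_rng(self, rng: np.random.Generator) -> None:
        """Share one generator across the whole module tree (dropout masks)."""
        for m in self.modules():
            m.rng = rng

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- computation -------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


class Sequential(Module):
    def __init__(self, layers: list[Module]):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Parallel(Module):
    """Feed the same input to each branch; concatenate outputs on channels."""

    def __init__(self, branches: list[Module], axis: int = -1):
        super().__init__()
        self.branches = list(branches)
        self.axis = axis
        self._splits: list[int] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        outs = [b.forward(x, train=train) for b in self.branches]
        shapes = {o.shape[:-1] for o in outs}
        if len(shapes) > 1:
            raise ShapeError(
                f"branch outputs do not align for concatenation: "
                f"{[o.shape for o in outs]}"
            )
        self._splits = [o.shape[self.axis] for o in outs]
        return np.concatenate(outs, axis=self.axis)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        edges = np.cumsum(self._splits)[:-1]
        parts = np.split(grad, edges, axis=self.axis)
        dx = None
        for branch, part in zip(self.branches, parts):
            g = branch.backward(np.ascontiguousarray(part))
            dx = g if dx is None else dx + g
        return dx
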