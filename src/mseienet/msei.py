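"""Multi-scale EEG-inception feature extractor (MSEI).

Three parallel scales process the raw ``(L, C, 1)`` window:

- **Main**: a three-branch temporal-convolution block (kernels 500/250/125,
  8 filters each), per-branch depthwise spatial convolutions (kernel ``(1,3)``,
  depth 2), concat, average-pool (4,1), a second three-branch block (kernels
  125/62/31, 8 filters on the 48-channel map), concat, average-pool (2,1),
  then efficient channel attention (ECA).
- **Aux1** / **Aux2**: a single three-branch block (kernels 125/64/32 and
  32/16/8, 4 filters), depthwise, concat, average-pool (8,1), ECA.

Each scale maps ``(1000, 3, 1)`` to ``(125, 1, 24)``; their concatenation is
the ``(125, 1, 72)`` feature map handed to the encoder (the trailing
average-pool of the concatenation is a size-(1,1) no-op, kept for structural
fidelity).

Scales are described declaratively (:class:`ScaleSpec`), compiled to a layer
plan with closed-form shape and parameter accounting (:func:`build_scale`) —
no instantiation needed to audit an architecture — and instantiated to a
trainable module on demand (:func:`instantiate_scale`).

Parameter conventions (these reproduce the reference Aux1/Aux2 totals of
1116 and 456 exactly): temporal convolutions carry biases; depthwise
convolutions carry none; batch normalization contributes 4 parameters per
channel (scale, shift, moving mean, moving variance); the ECA 1-D convolution
has k weights plus one bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "ConvBranchSpec",
    "EcaSpec",
    "ScaleSpec",
    "LayerPlan",
    "ScalePlan",
    "eca_kernel_size",
    "build_scale",
    "count_parameters",
    "instantiate_scale",
    "msei_forward",
    "main_scale_spec",
    "aux_scale_spec",
    "default_scale_specs",
]


@dataclass(frozen=True)
class ConvBranchSpec:
    """One temporal-convolution branch: kernel ``(kernel_len, 1)``, stride 1,
    'same' padding, ELU activation, dropout."""

    kernel_len: int
    filters: int
    dropout: float = 0.25

    def __post_init__(self) -> None:
        if self.kernel_len < 1 or self.filters < 1:
            raise ValueError("kernel_len and filters must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError(f"dropout must be in [0, 1); got {self.dropout}")


@dataclass(frozen=True)
class EcaSpec:
    """Efficient channel attention constants (k is derived from C)."""

    gamma: float = 2.0
    b: float = 1.0


@dataclass(frozen=True)
class ScaleSpec:
    """Declarative description of one MSEI scale."""

    name: str
    block1: tuple[ConvBranchSpec, ConvBranchSpec, ConvBranchSpec]
    depthwise_depth: int = 2
    pool1: int = 8
    block2: tuple[ConvBranchSpec, ConvBranchSpec, ConvBranchSpec] | None = None
    pool2: int | None = None
    eca: EcaSpec = field(default_factory=EcaSpec)
    dropout: float = 0.25

    def __post_init__(self) -> None:
        if (self.block2 is None) != (self.pool2 is None):
            raise ValueError("block2 and pool2 must be given together")


def eca_kernel_size(C: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Adaptive ECA kernel: nearest odd integer to ``|log2(C)/gamma + b/gamma|``.

    Ties round up; the result is at least 1.
    """
    if C < 1:
        raise ValueError(f"channel count must be >= 1; got {C}")
    v = abs(math.log2(C) / gamma + b / gamma)
    k = 2 * int(math.floor((v - 1.0) / 2.0 + 0.5)) + 1
    return max(k, 1)


@dataclass(frozen=True)
class LayerPlan:
    """One layer of a compiled plan: name, output shape, parameter count."""

    name: str
    output_shape: tuple[int, int, int]
    n_params: int = 0


@dataclass(frozen=True)
class ScalePlan:
    """Ordered layer plan for one scale with exact parameter accounting."""

    spec: ScaleSpec
    input_shape: tuple[int, int, int]
    layers: tuple[LayerPlan, ...]

    @property
    def output_shape(self) -> tuple[int, int, int]:
        return self.layers[-1].output_shape

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)


def _conv_block_plans(
    block: tuple[ConvBranchSpec, ...], shape: tuple[int, int, int], tag: str
) -> tuple[list[LayerPlan], tuple[int, int, int]]:
    """Three parallel Conv->BN->ELU->Dropout branches, concatenated."""
    T, S, C = shape
    plans = []
    for i, br in enumerate(block, start=1):
        n_conv = br.kernel_len * C * br.filters + br.filters
        plans.append(LayerPlan(f"{tag}.branch{i}.conv({br.kernel_len},1)x{br.filters}",
                               (T, S, br.filters), n_conv))
        plans.append(LayerPlan(f"{tag}.branch{i}.bn", (T, S, br.filters),
                               4 * br.filters))
    out_c = sum(br.filters for br in block)
    plans.append(LayerPlan(f"{tag}.concat", (T, S, out_c)))
    return plans, (T, S, out_c)


def build_scale(spec: ScaleSpec, input_shape: tuple[int, int, int]) -> ScalePlan:
    """Compile a :class:`ScaleSpec` into an ordered layer plan.

    Shapes and parameter counts are computed in closed form; pooling requires
    exact divisibility of the temporal length.
    """
    L, C, ch_in = input_shape
    if ch_in != 1:
        raise nn.ShapeError(f"scale input must be (L, C, 1); got {input_shape}")
    layers: list[LayerPlan] = []
    # block 1: per-branch conv then depthwise spatial filter, then concat
    T, S = L, C
    for i, br in enumerate(spec.block1, start=1):
        layers.append(LayerPlan(
            f"block1.branch{i}.conv({br.kernel_len},1)x{br.filters}",
            (T, S, br.filters), br.kernel_len * 1 * br.filters + br.filters))
        layers.append(LayerPlan(f"block1.branch{i}.bn", (T, S, br.filters),
                                4 * br.filters))
        dw_out = br.filters * spec.depthwise_depth
        layers.append(LayerPlan(
            f"block1.branch{i}.dwconv(1,{S})d{spec.depthwise_depth}",
            (T, 1, dw_out), S * br.filters * spec.depthwise_depth))
        layers.append(LayerPlan(f"block1.branch{i}.dwbn", (T, 1, dw_out),
                                4 * dw_out))
    c_cat = sum(br.filters for br in spec.block1) * spec.depthwise_depth
    layers.append(LayerPlan("block1.concat", (T, 1, c_cat)))
    if T % spec.pool1:
        raise nn.ShapeError(
            f"{spec.name}: AvgPool({spec.pool1},1) needs L divisible; L={T}"
        )
    T //= spec.pool1
    layers.append(LayerPlan(f"avgpool({spec.pool1},1)", (T, 1, c_cat)))
    shape = (T, 1, c_cat)
    if spec.block2 is not None:
        plans, shape = _conv_block_plans(spec.block2, shape, "block2")
        layers.extend(plans)
        T, S2, c2 = shape
        if T % spec.pool2:
            raise nn.ShapeError(
                f"{spec.name}: AvgPool({spec.pool2},1) needs divisibility; T={T}"
            )
        T //= spec.pool2
        shape = (T, S2, c2)
        layers.append(LayerPlan(f"avgpool({spec.pool2},1)", shape))
    k = eca_kernel_size(shape[2], spec.eca.gamma, spec.eca.b)
    layers.append(LayerPlan(f"eca(k={k})", shape, k + 1))
    return ScalePlan(spec=spec, input_shape=input_shape, layers=tuple(layers))


def count_parameters(plan: ScalePlan) -> int:
    """Total parameter count of a compiled plan (batch-norm statistics
    included)."""
    return plan.n_params


def _branch_module(
    br: ConvBranchSpec, in_shape: tuple[int, int], depth: int,
    rng: np.random.Generator, dtype,
) -> nn.Sequential:
    S = in_shape[1]
    return nn.Sequential([
        nn.TemporalConv(br.kernel_len, 1, br.filters, rng, dtype),
        nn.BatchNorm(br.filters, dtype=dtype),
        nn.ELU(),
        nn.Dropout(br.dropout),
        nn.DepthwiseSpatialConv(S, br.filters, depth, rng, dtype),
        nn.BatchNorm(br.filters * depth, dtype=dtype),
        nn.ELU(),
        nn.Dropout(br.dropout),
    ])


def instantiate_scale(
    plan: ScalePlan, rng: np.random.Generator, dtype=np.float64
) -> nn.Module:
    """Materialize a compiled plan as a trainable module.

    The instantiated module's own parameter count (summing every parameter
    array and buffer) equals ``plan.n_params`` — kept as a tested invariant.
    """
    spec = plan.spec
    L, C, _ = plan.input_shape
    layers: list[nn.Module] = [
        nn.Parallel([
            _branch_module(br, (L, C), spec.depthwise_depth, rng, dtype)
            for br in spec.block1
        ]),
        nn.AvgPoolTime(spec.pool1),
    ]
    if spec.block2 is not None:
        c_cat = sum(br.filters for br in spec.block1) * spec.depthwise_depth
        layers.append(nn.Parallel([
            nn.Sequential([
                nn.TemporalConv(br.kernel_len, c_cat, br.filters, rng, dtype),
                nn.BatchNorm(br.filters, dtype=dtype),
                nn.ELU(),
                nn.Dropout(br.dropout),
            ])
            for br in spec.block2
        ]))
        layers.append(nn.AvgPoolTime(spec.pool2))
    out_c = plan.output_shape[2]
    k = eca_kernel_size(out_c, spec.eca.gamma, spec.eca.b)
    layers.append(nn.ECA(out_c, k, rng, dtype))
    return nn.Sequential(layers)


def msei_forward(
    scales: list[nn.Module], x: np.ndarray, train: bool = False
) -> np.ndarray:
    """Run the three scales on ``x`` and concatenate on the feature axis.

    ``x`` is ``(B, L, C, 1)``; the output for the default geometry is
    ``(B, 125, 1, 72)``.  The trailing average-pool of the concatenation is a
    size-(1,1) no-op and is omitted.
    """
    outs = [s.forward(x, train=train) for s in scales]
    shapes = {o.shape[:3] for o in outs}
    if len(shapes) > 1:
        raise nn.ShapeError(
            f"scale outputs do not align for concatenation: "
            f"{[o.shape for o in outs]}"
        )
    return np.concatenate(outs, axis=-1)


# -- reference architecture ----------------------------------------------

def main_scale_spec(filters: int = 8, dropout: float = 0.25) -> ScaleSpec:
    """Main scale: kernels 500/250/125 then 125/62/31 (the fractional
    quarter-kernels are rounded down), pools (4,1) and (2,1)."""
    return ScaleSpec(
        name="Main",
        block1=tuple(ConvBranchSpec(k, filters, dropout) for k in (500, 250, 125)),
        depthwise_depth=2,
        pool1=4,
        block2=tuple(ConvBranchSpec(k, filters, dropout) for k in (125, 62, 31)),
        pool2=2,
        dropout=dropout,
    )


def aux_scale_spec(
    name: str, kernels: tuple[int, int, int], filters: int = 4,
    dropout: float = 0.25, pool: int = 8,
) -> ScaleSpec:
    """Auxiliary scale: one three-branch block, depthwise, pool (8,1), ECA."""
    return ScaleSpec(
        name=name,
        block1=tuple(ConvBranchSpec(k, filters, dropout) for k in kernels),
        depthwise_depth=2,
        pool1=pool,
        dropout=dropout,
    )


def default_scale_specs(
    filters_main: int = 8, filters_aux: int = 4, dropout: float = 0.25
) -> tuple[ScaleSpec, ScaleSpec, ScaleSpec]:
    """The (Main, Aux1, Aux2) trio of the reference architecture."""
    return (
        main_scale_spec(filters_main, dropout),
        aux_scale_spec("Aux1", (125, 64, 32), filters_aux, dropout),
        aux_scale_spec("Aux2", (32, 16, 8), filters_aux, dropout),
    )
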