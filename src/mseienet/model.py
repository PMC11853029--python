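"""Full classifier: MSEI -> encoder -> output head; training; ablation variants.

The assembled network maps an EEG window ``(L, C, 1)`` through the three MSEI
scales (concatenated to a ``(L/8, 1, channels)`` feature map), reads the
feature channels as tokens for the two-layer self-attention encoder, folds the
tokens back into a feature map and classifies through two temporal
convolutions (kernels ``(8,1)`` and ``(4,1)``), a flatten and a softmax dense
layer.

Training minimizes categorical cross-entropy with Adam and early stopping on
validation loss.  Everything is seeded: the same seed, data and configuration
reproduce the loss history bitwise (single-threaded execution).

Presets: ``full`` matches the reference architecture (463,866-parameter
scale); ``reduced`` halves every filter count, uses one encoder layer and
``d_ff = 64`` for desk-scale training runs; ``tiny`` additionally shrinks the
input geometry for fast protocol tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .core_io import EEGTrialSet
from .encoder import EncoderConfig, build_encoder, encoder_parameter_count
from .msei import (
    ConvBranchSpec,
    ScalePlan,
    ScaleSpec,
    aux_scale_spec,
    build_scale,
    default_scale_specs,
    instantiate_scale,
    main_scale_spec,
)

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "VariantSpec",
    "MSEIENet",
    "TrainingError",
    "DivergenceError",
    "assemble_model",
    "make_variant",
    "train",
    "predict",
    "accuracy",
    "parameter_table",
    "format_parameter_table",
    "model_config",
    "to_network_input",
    "REFERENCE_PARAMETER_COUNTS",
]

#: printed per-module parameter counts of the reference architecture, shown
#: next to this implementation's exact counts in parameter reports
REFERENCE_PARAMETER_COUNTS = {
    "Main scale": 90_764,
    "Aux1 scale": 1_116,
    "Aux2 scale": 456,
    "MSEI module": 92_336,
    "Encoder module": 345_750,
    "Output module": 25_780,
    "Total": 463_866,
}


class TrainingError(RuntimeError):
    pass


class DivergenceError(TrainingError):
    def __init__(self, epoch: int):
        super().__init__(f"loss became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class ModelConfig:
    """Architecture description; encoder token layout is derived from the
    MSEI output shape (tokens = feature channels, d_model = temporal length)."""

    input_len: int = 1000
    n_eeg_channels: int = 3
    scale_specs: tuple[ScaleSpec, ...] = field(
        default_factory=default_scale_specs
    )
    use_encoder: bool = True
    heads: int = 5
    n_encoder_layers: int = 2
    d_ff: int = 435
    encoder_dropout: float = 0.3
    head_filters: tuple[int, int] = (32, 12)
    head_dropout: float = 0.25
    n_classes: int = 4

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError(f"need at least 2 classes; got {self.n_classes}")
        if not self.scale_specs:
            raise ValueError("at least one scale spec is required")

    @property
    def input_shape(self) -> tuple[int, int, int]:
        return (self.input_len, self.n_eeg_channels, 1)

    def scale_plans(self) -> tuple[ScalePlan, ...]:
        return tuple(build_scale(s, self.input_shape) for s in self.scale_specs)

    def encoder_config(self) -> EncoderConfig:
        plans = self.scale_plans()
        shapes = {p.output_shape for p in plans}
        if len(shapes) > 1:
            raise nn.ShapeError(
                f"scale output shapes differ, cannot concatenate: {shapes}"
            )
        T, S, C = plans[0].output_shape
        tokens = C * len(plans)
        return EncoderConfig(
            tokens=tokens,
            d_model=T,
            heads=self.heads,
            n_layers=self.n_encoder_layers,
            d_ff=self.d_ff,
            dropout=self.encoder_dropout,
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam, cross-entropy, early stopping)."""

    learning_rate: float = 0.0005
    batch_size: int = 256
    epochs: int = 100
    patience: int = 10
    min_delta: float = 0.0
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @classmethod
    def binary(cls, **kw) -> "TrainConfig":
        """Reference setting for 2-class decoding: lr 1e-4, batch 128."""
        return cls(learning_rate=0.0001, batch_size=128, **kw)

    @classmethod
    def multitask(cls, **kw) -> "TrainConfig":
        """Reference setting for 4-class decoding: lr 5e-4, batch 256."""
        return cls(learning_rate=0.0005, batch_size=256, **kw)


@dataclass(frozen=True)
class VariantSpec:
    """One of the four ablation edits.

    1: Main scale only, no encoder.  2: full MSEI, no encoder.
    3: Main block-1 kernels exchanged with Aux1's.  4: with Aux2's.
    """

    variant_id: int

    def __post_init__(self) -> None:
        if self.variant_id not in (1, 2, 3, 4):
            raise ValueError(f"variant id must be 1..4; got {self.variant_id}")


def _with_kernels(spec: ScaleSpec, block1=None, block2=None) -> ScaleSpec:
    def rebuild(block, kernels):
        return tuple(
            ConvBranchSpec(k, br.filters, br.dropout)
            for k, br in zip(kernels, block)
        )
    changes = {}
    if block1 is not None:
        changes["block1"] = rebuild(spec.block1, block1)
    if block2 is not None:
        changes["block2"] = rebuild(spec.block2, block2)
    return replace(spec, **changes)


def make_variant(config: ModelConfig, spec: VariantSpec) -> ModelConfig:
    """Apply one ablation edit to an architecture configuration."""
    main, aux1, aux2 = None, None, None
    if len(config.scale_specs) == 3:
        main, aux1, aux2 = config.scale_specs
    vid = spec.variant_id
    if vid == 1:
        if main is None:
            main = config.scale_specs[0]
        return replace(config, scale_specs=(main,), use_encoder=False)
    if vid == 2:
        return replace(config, use_encoder=False)
    if main is None:
        raise ValueError("kernel-swap variants need the three-scale architecture")
    if vid == 3:
        return replace(config, scale_specs=(
            _with_kernels(main, block1=(125, 64, 32), block2=(32, 16, 8)),
            _with_kernels(aux1, block1=(500, 250, 125)),
            aux2,
        ))
    return replace(config, scale_specs=(
        _with_kernels(main, block1=(32, 16, 8), block2=(8, 4, 2)),
        aux1,
        _with_kernels(aux2, block1=(500, 250, 125)),
    ))


class MSEIENet(nn.Module):
    """The assembled trainable classifier."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float64):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        self.dtype = dtype
        plans = config.scale_plans()
        enc_cfg = config.encoder_config()
        self.plans = plans
        self.enc_cfg = enc_cfg
        self.msei = nn.Parallel([
            instantiate_scale(p, rng, dtype) for p in plans
        ])
        f1, f2 = config.head_filters
        stages: list[nn.Module] = [self.msei]
        if config.use_encoder:
            stages += [
                nn.Tokenize(),
                build_encoder(enc_cfg, rng, dtype),
                nn.Untokenize(),
            ]
        stages += [
            nn.TemporalConv(8, enc_cfg.tokens, f1, rng, dtype),
            nn.ELU(),
            nn.Dropout(config.head_dropout),
            nn.TemporalConv(4, f1, f2, rng, dtype),
            nn.ELU(),
            nn.Dropout(config.head_dropout),
            nn.Flatten(),
            nn.Dense(enc_cfg.d_model * f2, config.n_classes, rng, dtype),
        ]
        self.net = nn.Sequential(stages)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x.astype(self.dtype, copy=False), train=train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)


def assemble_model(
    config: ModelConfig, seed: int = 0, dtype=np.float32
) -> MSEIENet:
    """Build the classifier; raises a shape error naming the junction if the
    modules cannot be connected (e.g. d_model not divisible by the head
    count)."""
    return MSEIENet(config, seed=seed, dtype=dtype)


# -- parameter accounting -------------------------------------------------

def _head_parameter_count(config: ModelConfig) -> int:
    enc_cfg = config.encoder_config()
    f1, f2 = config.head_filters
    conv1 = 8 * enc_cfg.tokens * f1 + f1
    conv2 = 4 * f1 * f2 + f2
    dense = enc_cfg.d_model * f2 * config.n_classes + config.n_classes
    return conv1 + conv2 + dense


def parameter_table(config: ModelConfig) -> list[dict]:
    """Per-module parameter accounting in the reference-report format.

    Counts are closed-form (no instantiation) and include batch-norm moving
    statistics; ``reference`` carries the printed counts of the reference
    architecture where a row has one, for side-by-side comparison.
    """
    plans = config.scale_plans()
    enc_cfg = config.encoder_config()
    in_shape = config.input_shape
    out_shape = plans[0].output_shape
    rows = []
    names = ("Main scale", "Aux1 scale", "Aux2 scale")
    for plan, name in zip(plans, names):
        rows.append({
            "module": name,
            "input_shape": f"{in_shape[0]} x {in_shape[1]} x {in_shape[2]}",
            "output_shape": f"{out_shape[0]} x {out_shape[1]} x {out_shape[2]}",
            "n_params": plan.n_params,
        })
    msei_out = (out_shape[0], out_shape[1], out_shape[2] * len(plans))
    rows.append({
        "module": "MSEI module",
        "input_shape": "-",
        "output_shape": f"{msei_out[0]} x {msei_out[1]} x {msei_out[2]}",
        "n_params": sum(p.n_params for p in plans),
    })
    if config.use_encoder:
        rows.append({
            "module": "Encoder module",
            "input_shape": f"{enc_cfg.tokens} x {enc_cfg.d_model}",
            "output_shape": f"{enc_cfg.tokens} x {enc_cfg.d_model}",
            "n_params": encoder_parameter_count(enc_cfg),
        })
    rows.append({
        "module": "Output module",
        "input_shape": f"{msei_out[0]} x {msei_out[1]} x {msei_out[2]}",
        "output_shape": str(config.n_classes),
        "n_params": _head_parameter_count(config),
    })
    rows.append({
        "module": "Total",
        "input_shape": "-",
        "output_shape": "-",
        "n_params": sum(
            r["n_params"] for r in rows if r["module"] != "MSEI module"
        ),
    })
    # the published counts only describe the full reference architecture
    is_reference = config == ModelConfig(n_classes=config.n_classes)
    for r in rows:
        r["reference"] = (
            REFERENCE_PARAMETER_COUNTS.get(r["module"]) if is_reference else None
        )
    return rows


def format_parameter_table(rows: list[dict]) -> str:
    header = f"{'Layer':<16}{'Input':>18}{'Output':>18}{'Params':>12}{'Reference':>12}"
    lines = [header, "-" * len(header)]
    for r in rows:
        ref = "-" if r.get("reference") is None else f"{r['reference']:,}"
        lines.append(
            f"{r['module']:<16}{r['input_shape']:>18}{r['output_shape']:>18}"
            f"{r['n_params']:>12,}{ref:>12}"
        )
    return "\n".join(lines)


# -- presets ---------------------------------------------------------------

def model_config(
    preset: str = "full", input_len: int = 1000, n_classes: int = 4
) -> ModelConfig:
    """Named architecture presets.

    ``full``: the reference architecture.  ``reduced``: every filter count
    halved, one encoder layer, ``d_ff = 64`` — trainable on a CPU in minutes.
    ``tiny``: reduced further with a 200-sample input geometry, for protocol
    tests.
    """
    if preset == "full":
        return ModelConfig(input_len=input_len, n_classes=n_classes)
    if preset == "reduced":
        return ModelConfig(
            input_len=input_len,
            scale_specs=default_scale_specs(filters_main=4, filters_aux=2),
            n_encoder_layers=1,
            d_ff=64,
            head_filters=(16, 6),
            n_classes=n_classes,
        )
    if preset == "tiny":
        return ModelConfig(
            input_len=200,
            scale_specs=(
                ScaleSpec(
                    name="Main",
                    block1=tuple(ConvBranchSpec(k, 2) for k in (100, 50, 25)),
                    pool1=4,
                    block2=tuple(ConvBranchSpec(k, 2) for k in (25, 12, 6)),
                    pool2=2,
                ),
                aux_scale_spec("Aux1", (25, 13, 7), filters=1),
                aux_scale_spec("Aux2", (8, 4, 2), filters=1),
            ),
            n_encoder_layers=1,
            d_ff=16,
            head_filters=(4, 2),
            n_classes=n_classes,
        )
    raise ValueError(f"unknown preset {preset!r}; use full, reduced or tiny")


# -- config serialization --------------------------------------------------

def save_model_config(config: ModelConfig, path) -> None:
    """Write an architecture configuration as a YAML file mirroring the
    layer tables (kernels, filters, pools, dropout per scale)."""
    import yaml

    def scale_dict(s: ScaleSpec) -> dict:
        d = {
            "name": s.name,
            "block1": [[b.kernel_len, b.filters, b.dropout] for b in s.block1],
            "depthwise_depth": s.depthwise_depth,
            "pool1": s.pool1,
        }
        if s.block2 is not None:
            d["block2"] = [[b.kernel_len, b.filters, b.dropout]
                           for b in s.block2]
            d["pool2"] = s.pool2
        return d

    payload = {
        "input_len": config.input_len,
        "n_eeg_channels": config.n_eeg_channels,
        "n_classes": config.n_classes,
        "use_encoder": config.use_encoder,
        "heads": config.heads,
        "n_encoder_layers": config.n_encoder_layers,
        "d_ff": config.d_ff,
        "encoder_dropout": config.encoder_dropout,
        "head_filters": list(config.head_filters),
        "head_dropout": config.head_dropout,
        "scales": [scale_dict(s) for s in config.scale_specs],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_model_config(path) -> ModelConfig:
    """Read a configuration written by :func:`save_model_config`."""
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)

    def branches(entries):
        return tuple(ConvBranchSpec(k, f, d) for k, f, d in entries)

    scales = tuple(
        ScaleSpec(
            name=s["name"],
            block1=branches(s["block1"]),
            depthwise_depth=s.get("depthwise_depth", 2),
            pool1=s["pool1"],
            block2=branches(s["block2"]) if "block2" in s else None,
            pool2=s.get("pool2"),
        )
        for s in payload["scales"]
    )
    return ModelConfig(
        input_len=payload["input_len"],
        n_eeg_channels=payload["n_eeg_channels"],
        scale_specs=scales,
        use_encoder=payload["use_encoder"],
        heads=payload["heads"],
        n_encoder_layers=payload["n_encoder_layers"],
        d_ff=payload["d_ff"],
        encoder_dropout=payload["encoder_dropout"],
        head_filters=tuple(payload["head_filters"]),
        head_dropout=payload["head_dropout"],
        n_classes=payload["n_classes"],
    )


# -- training and inference ------------------------------------------------

def to_network_input(trials: EEGTrialSet, dtype=np.float32) -> np.ndarray:
    """``(N, C, T)`` trials to channels-last network input ``(N, T, C, 1)``."""
    return np.ascontiguousarray(
        trials.data.transpose(0, 2, 1)[..., None].astype(dtype)
    )


def _eval_loss(model: MSEIENet, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    total, n = 0.0, x.shape[0]
    for i in range(0, n, batch):
        logits = model.forward(x[i : i + batch], train=False)
        loss, _, _ = nn.softmax_cross_entropy(logits, y[i : i + batch])
        total += loss * logits.shape[0]
    return total / n


def train(
    model: MSEIENet,
    train_set: EEGTrialSet,
    val_set: EEGTrialSet | None,
    config: TrainConfig,
    verbose: bool = False,
) -> tuple[MSEIENet, dict]:
    """Fit with Adam + cross-entropy; early-stop on validation loss.

    Returns the fitted model and a history dict with per-epoch ``train_loss``
    and ``val_loss`` lists, plus ``best_epoch`` and ``stopped_epoch``.
    """
    if train_set.n_trials == 0:
        raise TrainingError("training set is empty")
    x = to_network_input(train_set, model.dtype)
    y = train_set.labels
    if y.max() >= model.config.n_classes:
        raise TrainingError(
            f"label {y.max()} out of range for {model.config.n_classes} classes"
        )
    xv = yv = None
    if val_set is not None and val_set.n_trials:
        xv = to_network_input(val_set, model.dtype)
        yv = val_set.labels
    rng = np.random.default_rng(config.seed)
    model.set_rng(rng)
    optimizer = nn.Adam(
        model.parameters(), lr=config.learning_rate,
        beta1=config.beta1, beta2=config.beta2,
    )
    history: dict = {"train_loss": [], "val_loss": [], "best_epoch": None,
                     "stopped_epoch": None}
    best_val = np.inf
    wait = 0
    for epoch in range(config.epochs):
        order = rng.permutation(x.shape[0])
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            model.zero_grad()
            logits = model.forward(x[idx], train=True)
            loss, dlogits, _ = nn.softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            model.backward(dlogits.astype(model.dtype))
            optimizer.step()
            epoch_loss += loss * len(idx)
            seen += len(idx)
        history["train_loss"].append(epoch_loss / seen)
        if xv is not None:
            vloss = _eval_loss(model, xv, yv, config.batch_size)
            if not np.isfinite(vloss):
                raise DivergenceError(epoch)
            history["val_loss"].append(vloss)
            if vloss < best_val - config.min_delta:
                best_val = vloss
                history["best_epoch"] = epoch
                wait = 0
            else:
                wait += 1
                if wait >= config.patience:
                    history["stopped_epoch"] = epoch
                    break
        if verbose:
            msg = f"epoch {epoch + 1}: train loss {history['train_loss'][-1]:.4f}"
            if history["val_loss"]:
                msg += f", val loss {history['val_loss'][-1]:.4f}"
            print(msg)
    return model, history


def predict(
    model: MSEIENet, trials: EEGTrialSet, batch_size: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels (argmax, lowest index on ties) and row-normalized
    class probabilities."""
    x = to_network_input(trials, model.dtype)
    probs = []
    for i in range(0, x.shape[0], batch_size):
        logits = model.forward(x[i : i + batch_size], train=False)
        probs.append(nn.softmax(logits.astype(np.float64), axis=-1))
    p = np.concatenate(probs, axis=0)
    return p.argmax(axis=1), p


def accuracy(model: MSEIENet, trials: EEGTrialSet) -> float:
    labels, _ = predict(model, trials)
    return float((labels == trials.labels).mean())
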