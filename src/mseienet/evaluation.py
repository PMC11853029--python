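"""Confusion-matrix metrics, cross-validation protocols and the lr x dropout grid.

Metric definitions (one-vs-rest per class, counts from an M x M confusion
matrix with rows = true class, columns = predicted):

- ``PR = TP / (TP + FP)``, ``RE = TP / (TP + FN)``,
  ``F1 = 2 PR RE / (PR + RE)``
- ``ACC = trace / total`` (the binary TP/TN form generalized to M classes)
- ``MF1`` = unweighted mean of the *unrounded* per-class F1 values
- ``kappa = (P0 - Pe) / (1 - Pe)`` with ``P0 = ACC`` and chance agreement
  ``Pe = sum_i row_i * col_i / total^2``

Values are kept unrounded internally; display formatting rounds half-up to
two decimals.  ``MF1`` computed from rounded per-class F1 values can differ
in the last digit from the exact mean; both are reported and the exact one is
normative.

Cross-validation operates on *raw* trials: folds are assigned before any
augmentation, augmentation is applied to training partitions only, and every
run carries an audit trail proving that no raw trial contributes windows to
both a training and a test partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .augmentation import AugmentationConfig, augment_training_set
from .core_io import EEGTrialSet, ValidationError
from .model import (
    ModelConfig,
    TrainConfig,
    assemble_model,
    predict,
    train,
)

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "CvPlan",
    "confusion_matrix",
    "per_class_metrics",
    "overall_metrics",
    "metrics_report",
    "round_half_up",
    "global_cv",
    "loso_cv",
    "hyperparameter_grid",
    "default_harness",
]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half away from zero, matching printed-table conventions."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """M x M counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "class_names", tuple(self.class_names))
        m = len(self.class_names)
        if counts.shape != (m, m):
            raise ValidationError(
                f"confusion matrix shape {counts.shape} does not match "
                f"{m} classes"
            )
        if (counts < 0).any():
            raise ValidationError("confusion-matrix counts must be nonnegative")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and overall metrics, unrounded, percentages in [0, 100]."""

    precision: tuple[float, ...]
    recall: tuple[float, ...]
    f1: tuple[float, ...]
    accuracy: float
    mf1: float
    mf1_rounded_inputs: float
    kappa: float
    class_names: tuple[str, ...]
    undefined: tuple[str, ...] = field(default_factory=tuple)

    def rounded(self) -> dict:
        """Display form: half-up to 2 decimals (kappa to 2 as well)."""
        return {
            "per_class": {
                name: {
                    "PR": round_half_up(p),
                    "RE": round_half_up(r),
                    "F1": round_half_up(f),
                }
                for name, p, r, f in zip(
                    self.class_names, self.precision, self.recall, self.f1
                )
            },
            "ACC": round_half_up(self.accuracy),
            "MF1": round_half_up(self.mf1),
            "kappa": round_half_up(self.kappa),
        }


def confusion_matrix(
    true: Sequence[int], predicted: Sequence[int], n_classes: int,
    class_names: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Count matrix: entry (i, j) = number of samples with true i predicted j."""
    true = np.asarray(true, dtype=np.int64)
    predicted = np.asarray(predicted, dtype=np.int64)
    if true.shape != predicted.shape:
        raise ValidationError(
            f"true and predicted lengths differ: {true.shape} vs {predicted.shape}"
        )
    for name, arr in (("true", true), ("predicted", predicted)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValidationError(
                f"{name} labels outside 0..{n_classes - 1}: "
                f"range [{arr.min()}, {arr.max()}]"
            )
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (true, predicted), 1)
    if class_names is None:
        class_names = tuple(str(i) for i in range(n_classes))
    return ConfusionMatrix(counts=counts, class_names=tuple(class_names))


def per_class_metrics(
    cm: ConfusionMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """One-vs-rest precision, recall and F1 per class, in percent.

    A class with no predicted (or no true) instances has an undefined metric;
    it is reported as 0 and its name is returned in the ``undefined`` list.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(np.float64)
    tp = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    undefined = [
        name
        for name, c, r in zip(cm.class_names, col, row)
        if c == 0 or r == 0
    ]
    with np.errstate(invalid="ignore", divide="ignore"):
        pr = np.where(col > 0, tp / np.where(col > 0, col, 1), 0.0)
        re = np.where(row > 0, tp / np.where(row > 0, row, 1), 0.0)
        denom = pr + re
        f1 = np.where(denom > 0, 2 * pr * re / np.where(denom > 0, denom, 1), 0.0)
    return pr * 100, re * 100, f1 * 100, undefined


def overall_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(ACC %, exact MF1 %, kappa)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    p0 = np.trace(counts) / total
    pe = float((counts.sum(axis=1) * counts.sum(axis=0)).sum()) / total**2
    kappa = (p0 - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    _, _, f1, _ = per_class_metrics(cm)
    return p0 * 100, float(f1.mean()), kappa


def metrics_report(cm: ConfusionMatrix) -> MetricsReport:
    """Full report; also carries MF1 recomputed from rounded per-class F1s
    (the display-order artifact some tables print)."""
    pr, re, f1, undefined = per_class_metrics(cm)
    acc, mf1, kappa = overall_metrics(cm)
    # exact decimal mean of the rounded per-class values, then rounded again
    # for display — the order some printed tables use
    rounded = [Decimal(repr(round_half_up(v))) for v in f1]
    mf1_rounded = float(sum(rounded) / len(rounded))
    return MetricsReport(
        precision=tuple(pr),
        recall=tuple(re),
        f1=tuple(f1),
        accuracy=acc,
        mf1=mf1,
        mf1_rounded_inputs=mf1_rounded,
        kappa=kappa,
        class_names=cm.class_names,
        undefined=tuple(undefined),
    )


@dataclass(frozen=True)
class CvPlan:
    """Raw-trial fold assignment plus the audit trail of each evaluation."""

    scheme: str
    fold_test_indices: tuple[tuple[int, ...], ...]
    val_fraction: float
    seed: int

    def leakage_audit(self, n_trials: int) -> bool:
        """Folds must partition the raw trials: pairwise disjoint, all covered."""
        seen: set[int] = set()
        for fold in self.fold_test_indices:
            fold_set = set(fold)
            if seen & fold_set:
                return False
            seen |= fold_set
        return seen == set(range(n_trials))


def _train_eval_once(
    train_raw: EEGTrialSet,
    test_raw: EEGTrialSet,
    aug: AugmentationConfig | None,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    val_fraction: float,
    seed: int,
) -> ConfusionMatrix:
    """Augment the training portion only, hold out a stratified validation
    fraction, train and evaluate on untouched test trials."""
    idx = np.arange(train_raw.n_trials)
    n_classes = len(train_raw.class_names)
    if round(val_fraction * train_raw.n_trials) < n_classes:
        val_fraction = 0.0  # too few trials for a stratified validation split
    if 0 < val_fraction < 1:
        tr_idx, va_idx = train_test_split(
            idx, test_size=val_fraction, stratify=train_raw.labels,
            random_state=seed % (2**32),
        )
    else:
        tr_idx, va_idx = idx, None
    tr = train_raw.subset(tr_idx)
    val = train_raw.subset(va_idx) if va_idx is not None else None
    if aug is not None:
        tr = augment_training_set(tr, aug)
    model = assemble_model(model_cfg, seed=seed)
    model, _ = train(model, tr, val, train_cfg)
    pred, _ = predict(model, test_raw)
    return confusion_matrix(
        test_raw.labels, pred, model_cfg.n_classes, test_raw.class_names
    )


def global_cv(
    trials: EEGTrialSet,
    k: int,
    aug: AugmentationConfig | None,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    seed: int = 0,
    val_fraction: float = 0.1,
) -> dict:
    """Stratified k-fold cross-validation over pooled raw trials.

    Per fold: the test fold is untouched; a stratified ``val_fraction`` of the
    remaining trials is held out for early stopping; augmentation (if any) is
    applied to the training portion only.  Returns per-fold reports, the
    pooled confusion matrix/report and the :class:`CvPlan` audit.
    """
    if k < 2:
        raise ValueError(f"need k >= 2 folds; got {k}")
    counts = np.bincount(trials.labels, minlength=trials.n_classes)
    if (counts < k).any():
        lacking = [
            trials.class_names[i] for i in np.flatnonzero(counts < k)
        ]
        raise ValueError(
            f"classes {lacking} have fewer than k={k} trials; cannot stratify"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    fold_tests = []
    fold_reports = []
    pooled = np.zeros((trials.n_classes, trials.n_classes), dtype=np.int64)
    for fold_id, (train_idx, test_idx) in enumerate(
        skf.split(np.zeros(trials.n_trials), trials.labels)
    ):
        fold_tests.append(tuple(int(i) for i in test_idx))
        cm = _train_eval_once(
            trials.subset(train_idx), trials.subset(test_idx), aug,
            model_cfg, train_cfg, val_fraction, seed + fold_id,
        )
        pooled += cm.counts
        fold_reports.append(metrics_report(cm))
    plan = CvPlan(
        scheme=f"global-{k}fold",
        fold_test_indices=tuple(fold_tests),
        val_fraction=val_fraction,
        seed=seed,
    )
    pooled_cm = ConfusionMatrix(pooled, trials.class_names)
    return {
        "plan": plan,
        "fold_reports": fold_reports,
        "pooled_confusion": pooled_cm,
        "pooled_report": metrics_report(pooled_cm),
        "leakage_audit_passed": plan.leakage_audit(trials.n_trials),
    }


def loso_cv(
    subjects: Sequence[EEGTrialSet],
    aug: AugmentationConfig | None,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    seed: int = 0,
    val_fraction: float = 0.1,
) -> dict:
    """Leave-one-subject-out: each subject in turn is the unseen test set.

    Returns per-subject accuracies (percent) and their unweighted average,
    with per-subject confusion matrices.
    """
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    accs = []
    cms = []
    for held_out in range(len(subjects)):
        rest = [s for i, s in enumerate(subjects) if i != held_out]
        train_raw = rest[0].with_data(
            np.concatenate([s.data for s in rest], axis=0),
            np.concatenate([s.labels for s in rest]),
        )
        cm = _train_eval_once(
            train_raw, subjects[held_out], aug, model_cfg, train_cfg,
            val_fraction, seed + held_out,
        )
        acc, _, _ = overall_metrics(cm)
        accs.append(acc)
        cms.append(cm)
    return {
        "per_subject_accuracy": accs,
        "average_accuracy": float(np.mean(accs)),
        "confusions": cms,
    }


def default_harness(
    trials: EEGTrialSet,
    model_cfg: ModelConfig,
    base_train_cfg: TrainConfig,
    aug: AugmentationConfig | None = None,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> Callable[[float, float], float]:
    """Build a train/evaluate harness over a fixed stratified split.

    The returned callable maps ``(learning_rate, dropout)`` to test accuracy
    in percent; the split and seeds stay fixed across grid points so that only
    the hyperparameters vary.
    """
    idx = np.arange(trials.n_trials)
    tr_idx, te_idx = train_test_split(
        idx, test_size=test_fraction, stratify=trials.labels,
        random_state=seed % (2**32),
    )

    def harness(lr: float, dropout: float) -> float:
        from dataclasses import replace

        cfg = replace(
            model_cfg,
            encoder_dropout=dropout,
            head_dropout=dropout,
            scale_specs=tuple(
                replace(
                    s,
                    block1=tuple(replace(b, dropout=dropout) for b in s.block1),
                    block2=None if s.block2 is None else tuple(
                        replace(b, dropout=dropout) for b in s.block2
                    ),
                )
                for s in model_cfg.scale_specs
            ),
        )
        tcfg = replace(base_train_cfg, learning_rate=lr, seed=seed)
        cm = _train_eval_once(
            trials.subset(tr_idx), trials.subset(te_idx), aug, cfg, tcfg,
            val_fraction=0.0, seed=seed,
        )
        acc, _, _ = overall_metrics(cm)
        return acc

    return harness


def hyperparameter_grid(
    lr_values: Sequence[float],
    dropout_values: Sequence[float],
    harness: Callable[[float, float], float],
) -> np.ndarray:
    """Accuracy matrix (len(lr) x len(dropout)) from the supplied harness."""
    if not len(lr_values) or not len(dropout_values):
        raise ValueError("lr and dropout grids must be nonempty")
    table = np.zeros((len(lr_values), len(dropout_values)))
    for i, lr in enumerate(lr_values):
        for j, dr in enumerate(dropout_values):
            table[i, j] = harness(lr, dr)
    return table
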