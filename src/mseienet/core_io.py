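"""Trial container, archive I/O, channel selection and normalization.

EEG trials live in a single in-memory container, :class:`EEGTrialSet`, holding a
trial-major tensor ``(n_trials, n_channels, n_samples)`` together with integer
class labels, the sampling rate and channel / class names.  On disk the same
content is a single ``.npz`` archive with named arrays (``data``, ``labels``,
``fs``, ``channel_names``, ``class_names``) — self-describing and lossless.

Raw-format ingestion (GDF/EDF) is deliberately out of scope: established EEG
readers (e.g. MNE) produce arrays upstream, and this module consumes arrays
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "EEGTrialSet",
    "DatasetManifest",
    "ArchiveFormatError",
    "ValidationError",
    "read_trials",
    "write_trials",
    "select_channels",
    "zscore_normalize",
]

_ARCHIVE_KEYS = ("data", "labels", "fs", "channel_names", "class_names")


class ArchiveFormatError(ValueError):
    """Raised when an archive is missing one of the documented keys."""


class ValidationError(ValueError):
    """Raised when an :class:`EEGTrialSet` violates its invariants."""


@dataclass(frozen=True)
class EEGTrialSet:
    """Labeled multi-trial EEG container.

    Parameters
    ----------
    data
        Real-valued array of shape ``(n_trials, n_channels, n_samples)``.
        Amplitudes are in microvolts for raw recordings and dimensionless
        after normalization.
    labels
        Integer class id per trial, each in ``0..n_classes-1``.
    fs
        Sampling rate in Hz (``> 0``).
    channel_names
        Ordered channel labels, length ``n_channels``.
    class_names
        Ordered class labels, length ``n_classes``.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "channel_names", tuple(map(str, self.channel_names)))
        object.__setattr__(self, "class_names", tuple(map(str, self.class_names)))
        if data.ndim != 3:
            raise ValidationError(
                f"data must be (n_trials, n_channels, n_samples); got shape {data.shape}"
            )
        if labels.ndim != 1 or labels.shape[0] != data.shape[0]:
            raise ValidationError(
                f"labels length {labels.shape} does not match n_trials={data.shape[0]}"
            )
        if data.shape[1] != len(self.channel_names):
            raise ValidationError(
                f"channel_names has {len(self.channel_names)} entries for "
                f"{data.shape[1]} data channels"
            )
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive; got {self.fs}")
        if data.shape[2] < 1:
            raise ValidationError("n_samples must be >= 1")
        m = len(self.class_names)
        if labels.size and (labels.min() < 0 or labels.max() >= m):
            raise ValidationError(
                f"labels must lie in 0..{m - 1}; got range "
                f"[{labels.min()}, {labels.max()}]"
            )

    # -- convenience views -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def with_data(self, data: np.ndarray, labels: np.ndarray | None = None) -> "EEGTrialSet":
        """Return a copy with ``data`` (and optionally ``labels``) replaced."""
        return replace(
            self, data=data, labels=self.labels if labels is None else labels
        )

    def class_counts(self) -> dict[str, int]:
        """Trial count per class name, in class order."""
        counts = np.bincount(self.labels, minlength=self.n_classes)
        return {name: int(c) for name, c in zip(self.class_names, counts)}

    def subset(self, idx: Sequence[int] | np.ndarray) -> "EEGTrialSet":
        """Select trials by index, preserving order."""
        idx = np.asarray(idx, dtype=np.int64)
        return self.with_data(self.data[idx], self.labels[idx])


@dataclass(frozen=True)
class DatasetManifest:
    """Summary of a dataset: identifier, class map and per-split trial counts."""

    name: str
    label_map: Mapping[str, int]
    split_counts: Mapping[str, Mapping[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = sorted(self.label_map.values())
        if ids != list(range(len(self.label_map))):
            raise ValidationError(
                f"label_map must biject class names onto 0..M-1; got ids {ids}"
            )

    @property
    def n_classes(self) -> int:
        return len(self.label_map)

    @classmethod
    def from_trials(cls, name: str, splits: Mapping[str, EEGTrialSet]) -> "DatasetManifest":
        """Build a manifest from named splits of one dataset."""
        first = next(iter(splits.values()))
        label_map = {c: i for i, c in enumerate(first.class_names)}
        counts = {split: ts.class_counts() for split, ts in splits.items()}
        return cls(name=name, label_map=label_map, split_counts=counts)


def write_trials(trials: EEGTrialSet, path: str | Path) -> Path:
    """Write a trial set to a single-file ``.npz`` archive.

    The round trip ``read_trials(write_trials(x))`` reproduces ``x`` exactly
    (data values, labels, sampling rate and names).
    """
    path = Path(path)
    np.savez(
        path,
        data=trials.data,
        labels=trials.labels,
        fs=np.float64(trials.fs),
        channel_names=np.array(trials.channel_names, dtype=np.str_),
        class_names=np.array(trials.class_names, dtype=np.str_),
    )
    # np.savez appends .npz only when missing; report the real file name
    return path if path.suffix == ".npz" else path.with_name(path.name + ".npz")


def read_trials(path: str | Path) -> EEGTrialSet:
    """Load and validate a trial set from an archive written by ``write_trials``."""
    with np.load(Path(path), allow_pickle=False) as npz:
        missing = [k for k in _ARCHIVE_KEYS if k not in npz.files]
        if missing:
            raise ArchiveFormatError(
                f"archive {path} is missing required keys {missing}; "
                f"found {npz.files}"
            )
        return EEGTrialSet(
            data=npz["data"],
            labels=npz["labels"],
            fs=float(npz["fs"]),
            channel_names=tuple(npz["channel_names"].tolist()),
            class_names=tuple(npz["class_names"].tolist()),
        )


def select_channels(trials: EEGTrialSet, names: Sequence[str]) -> EEGTrialSet:
    """Return a trial set restricted to ``names``, in the requested order.

    Typical use is reducing a full montage to the sensorimotor channels
    C3, Cz and C4.
    """
    index = {c: i for i, c in enumerate(trials.channel_names)}
    unknown = [n for n in names if n not in index]
    if unknown:
        raise KeyError(
            f"unknown channel(s) {unknown}; available: {list(trials.channel_names)}"
        )
    idx = [index[n] for n in names]
    return replace(
        trials, data=trials.data[:, idx, :], channel_names=tuple(names)
    )


def zscore_normalize(trials: EEGTrialSet) -> EEGTrialSet:
    """Standardize each trial-channel trace to mean 0, standard deviation 1.

    Normalization makes additive-noise amplitudes (e.g. the augmentation
    default sigma = 0.005) meaningful relative to signal scale.  A trace with
    zero variance cannot be standardized and raises ``ValidationError``.
    """
    mean = trials.data.mean(axis=2, keepdims=True)
    sd = trials.data.std(axis=2, keepdims=True)
    flat = np.argwhere(sd[:, :, 0] == 0)
    if flat.size:
        t, c = flat[0]
        raise ValidationError(
            f"zero-variance trace in trial {t}, channel "
            f"{trials.channel_names[c]!r}: cannot z-score"
        )
    return trials.with_data((trials.data - mean) / sd)
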