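"""Training-set augmentation: spline interpolation, sliding window, Gaussian doubling.

Motor-imagery datasets are small, so the decoder's training set is expanded in
three steps applied to training data only (never to validation or test
trials, which are consumed at native length):

1. each trial of length T is resampled to U samples by a quadratic spline;
2. a sliding window of length w and stride s cuts each interpolated trial
   into ``floor((U - w)/s) + 1`` windows, each inheriting the trial label;
3. the window set is doubled by appending a copy with i.i.d. Gaussian noise
   N(mu, sigma^2) added elementwise.

With the defaults U = w + 4 s (w = 1000, s = 10, so U = 1040) each raw trial
yields 5 windows and, after doubling, exactly 10 training examples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_interp_spline

from .core_io import EEGTrialSet

__all__ = [
    "AugmentationConfig",
    "spline_interpolate",
    "sliding_window",
    "gaussian_copy",
    "augment_training_set",
    "n_windows",
]


def n_windows(U: int, w: int, s: int) -> int:
    """Number of windows a length-U trial yields: floor((U - w)/s) + 1."""
    if w > U:
        raise ValueError(f"window length {w} exceeds trial length {U}")
    if s < 1:
        raise ValueError(f"stride must be >= 1; got {s}")
    return (U - w) // s + 1


@dataclass(frozen=True)
class AugmentationConfig:
    """Parameters of the three-step pipeline.

    ``target_len`` (U) defaults to ``window_len + 4 * stride`` when omitted,
    which makes exactly 5 windows per trial and a 10x expansion overall.
    """

    window_len: int = 1000
    stride: int = 10
    target_len: int | None = None
    noise_mean: float = 0.0
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_len is None:
            object.__setattr__(self, "target_len", self.window_len + 4 * self.stride)
        if self.window_len > self.target_len:
            raise ValueError(
                f"window_len {self.window_len} exceeds target_len {self.target_len}"
            )
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1; got {self.stride}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0; got {self.noise_sd}")

    @property
    def windows_per_trial(self) -> int:
        return n_windows(self.target_len, self.window_len, self.stride)

    @property
    def expansion_factor(self) -> int:
        """Training examples emitted per raw trial (windows x Gaussian doubling)."""
        return 2 * self.windows_per_trial


def spline_interpolate(trials: EEGTrialSet, target_len: int) -> EEGTrialSet:
    """Resample every trial-channel trace to ``target_len`` samples.

    A quadratic (order-2) spline is fitted through the original samples placed
    at positions ``t * (U - 1) / (T - 1)`` and evaluated on the integer grid
    ``0..U-1``, so values at the original knot positions are preserved.
    """
    T = trials.n_samples
    if T < 3:
        raise ValueError(f"quadratic spline needs at least 3 samples; got T={T}")
    if target_len < T:
        raise ValueError(f"target_len {target_len} must be >= T={T}")
    if target_len == T:
        return trials.with_data(trials.data.copy())
    knots = np.arange(T) * (target_len - 1) / (T - 1)
    spline = make_interp_spline(knots, trials.data, k=2, axis=2)
    out = spline(np.arange(target_len))
    return trials.with_data(out)


def sliding_window(trials: EEGTrialSet, w: int, s: int) -> EEGTrialSet:
    """Cut each trial into windows of length ``w`` at stride ``s``.

    Window j covers samples ``[j*s, j*s + w)``; every window inherits its
    trial's label.  Output trials are ordered trial-major (all windows of
    trial 0, then trial 1, ...).
    """
    U = trials.n_samples
    k = n_windows(U, w, s)
    # (N, C, k, w) view over the sample axis, then fold windows into trials
    view = np.lib.stride_tricks.sliding_window_view(trials.data, w, axis=2)
    windows = view[:, :, :: s, :][:, :, :k, :]
    out = np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(
        trials.n_trials * k, trials.n_channels, w
    )
    labels = np.repeat(trials.labels, k)
    return trials.with_data(out, labels)


def gaussian_copy(
    trials: EEGTrialSet, mean: float = 0.0, sd: float = 0.005, seed: int = 0
) -> EEGTrialSet:
    """Same-shape copy with i.i.d. Gaussian noise added elementwise."""
    if sd < 0:
        raise ValueError(f"noise sd must be >= 0; got {sd}")
    rng = np.random.default_rng(seed)
    noise = rng.normal(mean, sd, size=trials.data.shape) if sd > 0 else mean
    return trials.with_data(trials.data + noise, trials.labels.copy())


def augment_training_set(trials: EEGTrialSet, config: AugmentationConfig) -> EEGTrialSet:
    """Full pipeline: interpolate -> window -> append Gaussian copies.

    Output size is ``2 * (floor((U - w)/s) + 1) * N`` trials of length ``w``;
    with the defaults this is 10 N.  Class balance is preserved exactly.
    """
    interp = spline_interpolate(trials, config.target_len)
    windows = sliding_window(interp, config.window_len, config.stride)
    noisy = gaussian_copy(windows, config.noise_mean, config.noise_sd, config.seed)
    data = np.concatenate([windows.data, noisy.data], axis=0)
    labels = np.concatenate([windows.labels, noisy.labels])
    return trials.with_data(data, labels)
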