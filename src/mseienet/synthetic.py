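"""Synthetic 4-class motor-imagery EEG with controllable ERD/ERS structure.

Motor imagery modulates band-limited power of the sensorimotor rhythms: mu
(8–12 Hz) and beta (~18–26 Hz) power decreases over the contralateral motor
cortex during imagined hand movement (event-related desynchronization, ERD)
and can increase in other conditions (ERS).  The generator emulates exactly
this signature: each channel is 1/f^alpha background noise plus mu- and
beta-band narrowband oscillators whose amplitudes are scaled per class and
channel, so class membership is carried by the spatial pattern of band power
at C3 / Cz / C4 — the feature a motor-imagery decoder must learn.

The default geometry (3 channels, 250 Hz, 4 s) mirrors the common
competition-data setting, so generated tensors have the same shapes the
decoder is designed around.  No volume-conduction or artifact realism is
attempted; see the methods note for what that implies about test coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core_io import EEGTrialSet

__all__ = [
    "SyntheticConfig",
    "ClassEffect",
    "default_class_effects",
    "generate_mi_trials",
    "bandpower",
]

#: canonical 4-class naming: left hand, right hand, feet, tongue
DEFAULT_CLASS_NAMES = ("L", "R", "F", "T")


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions for one synthetic dataset.

    ``effect_size`` in [0, 1] controls how strongly class-specific ERD/ERS
    modulates the oscillator amplitudes (0 = no class information, 1 = full
    suppression of the attenuated rhythm).  ``noise_sd`` is the amplitude of
    the 1/f^alpha background; oscillator base amplitudes are fixed at 1.0 (mu)
    and 0.5 (beta) so the rhythms ride visibly on, but do not dominate, the
    background.
    """

    n_trials_per_class: int = 21
    fs: float = 250.0
    duration: float = 4.0
    channels: tuple[str, ...] = ("C3", "Cz", "C4")
    mu_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (18.0, 26.0)
    background_exponent: float = 1.0
    effect_size: float = 0.8
    noise_sd: float = 1.0
    seed: int = 0
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    mu_amplitude: float = 1.0
    beta_amplitude: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError(f"effect_size must be in [0, 1]; got {self.effect_size}")
        n = self.fs * self.duration
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"fs * duration must be a positive integer sample count; got {n}"
            )
        nyq = self.fs / 2
        for band in (self.mu_band, self.beta_band):
            if not (0 < band[0] < band[1] < nyq):
                raise ValueError(f"band {band} must lie within (0, {nyq}) Hz")
        if self.n_trials_per_class < 0:
            raise ValueError("n_trials_per_class must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


@dataclass(frozen=True)
class ClassEffect:
    """Per-channel amplitude gains for one class (gain 1 = no modulation)."""

    class_id: int
    mu_gain: dict[str, float] = field(default_factory=dict)
    beta_gain: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gains in (self.mu_gain, self.beta_gain):
            bad = {ch: g for ch, g in gains.items() if g < 0}
            if bad:
                raise ValueError(f"gains must be nonnegative; got {bad}")


def default_class_effects(
    channels: tuple[str, ...] | list[str], effect_size: float
) -> list[ClassEffect]:
    """Contralateral ERD pattern for the 4 canonical classes.

    - class 0 (left hand): mu and beta attenuated at C4 by ``1 - effect_size``
    - class 1 (right hand): attenuated at C3
    - class 2 (feet): attenuated at Cz
    - class 3 (tongue): mu enhanced at C3 and C4 by ``1 + effect_size``
    """
    required = {"C3", "Cz", "C4"}
    missing = required - set(channels)
    if missing:
        raise ValueError(f"channels must include {sorted(required)}; missing {sorted(missing)}")
    if not 0.0 <= effect_size <= 1.0:
        raise ValueError(f"effect_size must be in [0, 1]; got {effect_size}")
    base = {ch: 1.0 for ch in channels}
    erd = 1.0 - effect_size
    ers = 1.0 + effect_size
    return [
        ClassEffect(0, mu_gain={**base, "C4": erd}, beta_gain={**base, "C4": erd}),
        ClassEffect(1, mu_gain={**base, "C3": erd}, beta_gain={**base, "C3": erd}),
        ClassEffect(2, mu_gain={**base, "Cz": erd}, beta_gain={**base, "Cz": erd}),
        ClassEffect(3, mu_gain={**base, "C3": ers, "C4": ers}, beta_gain=dict(base)),
    ]


def _pink_noise(rng: np.random.Generator, n: int, alpha: float, sd: float) -> np.ndarray:
    """1/f^alpha noise of length n, scaled to standard deviation ``sd``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-alpha / 2.0)
    shaping[0] = 0.0  # no DC drift
    trace = np.fft.irfft(spec * shaping, n)
    s = trace.std()
    return trace * (sd / s) if s > 0 else trace


def _oscillator(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance narrowband oscillator: band-limited Gaussian noise.

    White noise is masked to the band in the frequency domain (random phase
    at every in-band frequency), so each trial carries energy across the whole
    band — the stochastic character of real sensorimotor rhythms rather than a
    pure sinusoid.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    trace = np.fft.irfft(spec * mask, n)
    s = trace.std()
    return trace / s if s > 0 else trace


def generate_mi_trials(
    config: SyntheticConfig, effects: list[ClassEffect] | None = None
) -> EEGTrialSet:
    """Generate a balanced 4-class synthetic motor-imagery trial set.

    Each trial-channel trace is ``background + gain_mu * mu_osc + gain_beta *
    beta_osc`` with the gains taken from the class's :class:`ClassEffect`.
    Identical seeds produce bitwise-identical output.
    """
    if effects is None:
        effects = default_class_effects(config.channels, config.effect_size)
    if len(effects) != len(config.class_names):
        raise ValueError(
            f"need one ClassEffect per class; got {len(effects)} for "
            f"{len(config.class_names)} classes"
        )
    rng = np.random.default_rng(config.seed)
    n_per = config.n_trials_per_class
    n_samples = config.n_samples
    n_total = n_per * len(effects)
    data = np.empty((n_total, len(config.channels), n_samples))
    labels = np.empty(n_total, dtype=np.int64)
    i = 0
    for eff in effects:
        for _ in range(n_per):
            for c, ch in enumerate(config.channels):
                bg = _pink_noise(
                    rng, n_samples, config.background_exponent, config.noise_sd
                )
                mu = _oscillator(rng, n_samples, config.fs, config.mu_band)
                beta = _oscillator(rng, n_samples, config.fs, config.beta_band)
                data[i, c] = (
                    bg
                    + config.mu_amplitude * eff.mu_gain.get(ch, 1.0) * mu
                    + config.beta_amplitude * eff.beta_gain.get(ch, 1.0) * beta
                )
            labels[i] = eff.class_id
            i += 1
    return EEGTrialSet(
        data=data,
        labels=labels,
        fs=config.fs,
        channel_names=config.channels,
        class_names=config.class_names,
    )


def bandpower(trace: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Mean Welch PSD in ``band`` (segments of one second, 50% overlap)."""
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} must lie within (0, {fs / 2}) Hz")
    trace = np.asarray(trace, dtype=np.float64)
    nperseg = min(int(fs), trace.size)
    freqs, psd = signal.welch(trace, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no PSD bins at fs={fs}, n={trace.size}")
    return float(psd[mask].mean())
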