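"""Walk through the three-step training-set augmentation.

Each raw 1000-sample trial is spline-interpolated to 1040 samples, cut into
5 sliding windows (w=1000, stride 10), and the window set is doubled with
Gaussian-noise copies (sigma = 0.005) — 10 training examples per raw trial.
"""

from mseienet import (
    AugmentationConfig,
    SyntheticConfig,
    augment_training_set,
    generate_mi_trials,
    sliding_window,
    spline_interpolate,
    zscore_normalize,
)

trials = zscore_normalize(generate_mi_trials(
    SyntheticConfig(n_trials_per_class=21, seed=3)
))
print(f"raw:          {trials.n_trials} trials x {trials.n_samples} samples")

config = AugmentationConfig(window_len=1000, stride=10, noise_sd=0.005, seed=0)
interp = spline_interpolate(trials, config.target_len)
print(f"interpolated: {interp.n_trials} trials x {interp.n_samples} samples")

windows = sliding_window(interp, config.window_len, config.stride)
print(f"windowed:     {windows.n_trials} windows x {windows.n_samples} samples "
      f"({config.windows_per_trial} per trial)")

augmented = augment_training_set(trials, config)
print(f"augmented:    {augmented.n_trials} examples "
      f"({config.expansion_factor} per raw trial after Gaussian doubling)")
print("per-class counts:", augmented.class_counts())
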