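"""Run the two subject-independent evaluation protocols on synthetic data.

Global k-fold CV pools all trials and stratifies folds by class; the
leave-one-subject-out (LOSO) protocol holds out one simulated subject at a
time.  Both augment the training partition only — the printed audit confirms
no raw trial leaks between training and test.  Sizes are miniature so the
script finishes in seconds; at this scale the tiny model stays near the 25%
chance level — the point here is the protocol mechanics and the audit, not
accuracy (see train_decoder.py for a learning demonstration).
"""

from mseienet import (
    AugmentationConfig,
    SyntheticConfig,
    TrainConfig,
    generate_mi_trials,
    global_cv,
    loso_cv,
    model_config,
    zscore_normalize,
)

make = lambda seed: zscore_normalize(generate_mi_trials(SyntheticConfig(
    n_trials_per_class=10, duration=0.8, effect_size=0.9, seed=seed)))

model_cfg = model_config("tiny")
train_cfg = TrainConfig(learning_rate=1e-3, batch_size=16, epochs=6, seed=0)
aug = AugmentationConfig(window_len=200, stride=10, noise_sd=0.005, seed=0)

result = global_cv(make(1), k=2, aug=aug, model_cfg=model_cfg,
                   train_cfg=train_cfg, seed=0)
pooled = result["pooled_report"].rounded()
print("global 2-fold CV")
print(f"  pooled ACC {pooled['ACC']:.2f}%  MF1 {pooled['MF1']:.2f}%  "
      f"kappa {pooled['kappa']:.2f}")
print(f"  leakage audit passed: {result['leakage_audit_passed']}")

subjects = [make(seed) for seed in (10, 11, 12)]
loso = loso_cv(subjects, aug=None, model_cfg=model_cfg, train_cfg=train_cfg,
               seed=0, val_fraction=0.0)
print("\nleave-one-subject-out (3 simulated subjects)")
for i, acc in enumerate(loso["per_subject_accuracy"], start=1):
    print(f"  subject {i}: {acc:.2f}%")
print(f"  average:   {loso['average_accuracy']:.2f}%")
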