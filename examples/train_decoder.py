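"""Train a small decoder end to end on synthetic ERD/ERS trials.

Uses the ``tiny`` preset (short 0.8 s trials, minimal filter counts) so the
whole run takes about half a minute on a laptop CPU.  The tiny network is
deliberately undersized — it climbs well above the 25% chance level of the
4-class problem but does not saturate.  For a realistic-geometry run (4 s,
250 Hz trials, the ``reduced`` preset, ~100 trials per class, learning rate
1e-3, batch 16, up to 20 epochs) expect a few minutes and held-out accuracy
above 90%.
"""

from mseienet import (
    SyntheticConfig,
    TrainConfig,
    accuracy,
    assemble_model,
    generate_mi_trials,
    model_config,
    train,
    zscore_normalize,
)


def make(n_per_class, seed):
    return zscore_normalize(generate_mi_trials(SyntheticConfig(
        n_trials_per_class=n_per_class, duration=0.8, effect_size=0.9,
        seed=seed,
    )))


train_set, val_set, test_set = make(60, 1), make(8, 2), make(25, 3)
net = assemble_model(model_config("tiny"), seed=0)
print(f"tiny model: {net.count_parameters():,} parameters")

cfg = TrainConfig(learning_rate=1e-3, batch_size=16, epochs=60, patience=60,
                  seed=0)
net, history = train(net, train_set, val_set, cfg)
print(f"final train loss {history['train_loss'][-1]:.3f}, "
      f"val loss {history['val_loss'][-1]:.3f} "
      f"after {len(history['train_loss'])} epochs")

acc = accuracy(net, test_set)
print(f"held-out accuracy: {acc:.1%} (chance level 25%)")
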