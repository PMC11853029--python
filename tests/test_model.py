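import numpy as np
import pytest

from mseienet import (
    EEGTrialSet,
    ModelConfig,
    SyntheticConfig,
    TrainConfig,
    VariantSpec,
    assemble_model,
    generate_mi_trials,
    make_variant,
    model_config,
    parameter_table,
    predict,
    train,
)
from mseienet.core_io import zscore_normalize
from mseienet.model import TrainingError


def total_params(cfg: ModelConfig) -> int:
    return parameter_table(cfg)[-1]["n_params"]


@pytest.fixture(scope="module")
def tiny_trials() -> EEGTrialSet:
    cfg = SyntheticConfig(n_trials_per_class=6, duration=0.8, effect_size=0.9,
                          seed=21)
    return zscore_normalize(generate_mi_trials(cfg))


class TestAssembly:
    def test_tiny_model_outputs_class_probabilities(self, rng):
        net = assemble_model(model_config("tiny"), seed=0)
        x = rng.standard_normal((3, 200, 3, 1)).astype(np.float32)
        logits = net.forward(x)
        assert logits.shape == (3, 4)

    def test_softmax_rows_sum_to_one(self, tiny_trials):
        net = assemble_model(model_config("tiny"), seed=0)
        _, probs = predict(net, tiny_trials)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_parameter_table_contains_reference_aux_counts(self):
        rows = {r["module"]: r["n_params"] for r in
                parameter_table(model_config("full"))}
        assert rows["Aux1 scale"] == 1116
        assert rows["Aux2 scale"] == 456

    def test_closed_form_total_matches_instantiated_model(self):
        for preset in ("reduced", "tiny"):
            cfg = model_config(preset)
            net = assemble_model(cfg, seed=0)
            assert net.count_parameters() == total_params(cfg)

    def test_m_classes_validated(self):
        with pytest.raises(ValueError, match="classes"):
            model_config("tiny", n_classes=1)

    def test_yaml_config_round_trip(self, tmp_path):
        from mseienet.model import load_model_config, save_model_config

        for preset in ("full", "reduced"):
            cfg = model_config(preset)
            path = tmp_path / f"{preset}.yaml"
            save_model_config(cfg, path)
            assert load_model_config(path) == cfg


class TestVariants:
    def test_variant_1_is_main_scale_only_without_encoder(self):
        cfg = model_config("full")
        v1 = make_variant(cfg, VariantSpec(1))
        assert len(v1.scale_specs) == 1
        assert v1.scale_specs[0].name == "Main"
        assert not v1.use_encoder

    def test_variant_2_removes_only_the_encoder(self):
        cfg = model_config("full")
        v2 = make_variant(cfg, VariantSpec(2))
        assert v2.scale_specs == cfg.scale_specs
        assert not v2.use_encoder

    def test_variant_2_plus_encoder_restores_default(self):
        from dataclasses import replace

        cfg = model_config("full")
        v2 = make_variant(cfg, VariantSpec(2))
        assert replace(v2, use_encoder=True) == cfg

    def test_variant_3_swaps_main_and_aux1_kernels(self):
        cfg = model_config("full")
        v3 = make_variant(cfg, VariantSpec(3))
        main, aux1, aux2 = v3.scale_specs
        assert tuple(b.kernel_len for b in main.block1) == (125, 64, 32)
        assert tuple(b.kernel_len for b in main.block2) == (32, 16, 8)
        assert tuple(b.kernel_len for b in aux1.block1) == (500, 250, 125)
        assert aux2 == cfg.scale_specs[2]

    def test_variant_4_swaps_main_and_aux2_kernels(self):
        cfg = model_config("full")
        v4 = make_variant(cfg, VariantSpec(4))
        main, aux1, aux2 = v4.scale_specs
        assert tuple(b.kernel_len for b in main.block1) == (32, 16, 8)
        assert tuple(b.kernel_len for b in main.block2) == (8, 4, 2)
        assert tuple(b.kernel_len for b in aux2.block1) == (500, 250, 125)
        assert aux1 == cfg.scale_specs[1]

    def test_parameter_count_monotonicity(self):
        cfg = model_config("full")
        v1 = make_variant(cfg, VariantSpec(1))
        v2 = make_variant(cfg, VariantSpec(2))
        assert total_params(v1) < total_params(v2) < total_params(cfg)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="1..4"):
            VariantSpec(5)


class TestTraining:
    def test_zero_learning_rate_leaves_parameters_unchanged(self, tiny_trials):
        net = assemble_model(model_config("tiny"), seed=1)
        before = [p.value.copy() for p in net.parameters()]
        cfg = TrainConfig(learning_rate=0.0, batch_size=8, epochs=3, seed=0)
        net, history = train(net, tiny_trials, None, cfg)
        for p, b in zip(net.parameters(), before):
            np.testing.assert_array_equal(p.value, b)
        # loss varies only through dropout-mask noise, not optimization
        assert len(history["train_loss"]) == 3

    def test_same_seed_reproduces_loss_history(self, tiny_trials):
        cfg = TrainConfig(learning_rate=1e-3, batch_size=8, epochs=2, seed=5)
        histories = []
        for _ in range(2):
            net = assemble_model(model_config("tiny"), seed=1)
            _, h = train(net, tiny_trials, tiny_trials, cfg)
            histories.append(h)
        assert histories[0]["train_loss"] == histories[1]["train_loss"]
        assert histories[0]["val_loss"] == histories[1]["val_loss"]

    def test_empty_training_set_rejected(self, tiny_trials):
        net = assemble_model(model_config("tiny"), seed=0)
        empty = tiny_trials.subset(np.array([], dtype=int))
        with pytest.raises(TrainingError, match="empty"):
            train(net, empty, None, TrainConfig())

    def test_early_stopping_respects_patience(self, tiny_trials):
        # min_delta larger than any achievable improvement: only the first
        # epoch counts as an improvement, so training stops after `patience`
        # further epochs
        cfg = TrainConfig(learning_rate=1e-4, batch_size=8, epochs=30,
                          patience=3, min_delta=10.0, seed=0)
        net = assemble_model(model_config("tiny"), seed=0)
        _, history = train(net, tiny_trials, tiny_trials, cfg)
        assert history["stopped_epoch"] == 3
        assert len(history["val_loss"]) == 4

    def test_duplicated_inputs_predict_identically(self, tiny_trials):
        net = assemble_model(model_config("tiny"), seed=2)
        doubled = tiny_trials.with_data(
            np.concatenate([tiny_trials.data, tiny_trials.data]),
            np.concatenate([tiny_trials.labels, tiny_trials.labels]),
        )
        labels, probs = predict(net, doubled)
        n = tiny_trials.n_trials
        np.testing.assert_array_equal(labels[:n], labels[n:])
        np.testing.assert_array_equal(probs[:n], probs[n:])

    def test_reference_train_configs(self):
        assert TrainConfig.binary().learning_rate == 0.0001
        assert TrainConfig.binary().batch_size == 128
        assert TrainConfig.multitask().learning_rate == 0.0005
        assert TrainConfig.multitask().batch_size == 256
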