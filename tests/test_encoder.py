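import numpy as np
import pytest

from mseienet import nn
from mseienet.encoder import (
    EncoderConfig,
    build_encoder,
    encoder_forward,
    encoder_parameter_count,
    feed_forward,
    multi_head_attention,
    project_qkv,
    scaled_dot_attention,
)


def loop_attention(Q, K, V, d_k):
    """Double-loop softmax attention oracle."""
    n, m = Q.shape[0], K.shape[0]
    out = np.zeros((n, V.shape[1]))
    weights = np.zeros((n, m))
    for i in range(n):
        logits = np.array([Q[i] @ K[j] / np.sqrt(d_k) for j in range(m)])
        e = np.exp(logits - logits.max())
        weights[i] = e / e.sum()
        for j in range(m):
            out[i] += weights[i, j] * V[j]
    return out, weights


def random_params(rng, d_model, d_ff):
    def mat(a, b):
        return rng.standard_normal((a, b)) * 0.2
    return {
        "mha": {
            "Wq": mat(d_model, d_model), "Wk": mat(d_model, d_model),
            "Wv": mat(d_model, d_model), "Wo": mat(d_model, d_model),
            "bq": rng.standard_normal(d_model) * 0.1,
            "bk": rng.standard_normal(d_model) * 0.1,
            "bv": rng.standard_normal(d_model) * 0.1,
            "bo": rng.standard_normal(d_model) * 0.1,
        },
        "ffn": (mat(d_model, d_ff), rng.standard_normal(d_ff) * 0.1,
                mat(d_ff, d_model), rng.standard_normal(d_model) * 0.1),
        "ln1": (np.ones(d_model), np.zeros(d_model)),
        "ln2": (np.ones(d_model), np.zeros(d_model)),
    }


class TestProjections:
    def test_identity_projections(self, rng):
        E = rng.standard_normal((5, 4))
        eye = np.eye(4)
        Q, K, V = project_qkv(E, eye, eye, eye)
        for M in (Q, K, V):
            np.testing.assert_array_equal(M, E)

    def test_matches_matmul_oracle(self, rng):
        E = rng.standard_normal((3, 4))
        Ws = [rng.standard_normal((4, 4)) for _ in range(3)]
        bs = [rng.standard_normal(4) for _ in range(3)]
        Q, K, V = project_qkv(E, *Ws, *bs)
        oracle = np.array([[E[i] @ Ws[0][:, j] + bs[0][j] for j in range(4)]
                           for i in range(3)])
        np.testing.assert_allclose(Q, oracle, atol=1e-6)

    def test_zero_input_zero_output(self, rng):
        E = np.zeros((2, 4))
        W = rng.standard_normal((4, 4))
        Q, _, _ = project_qkv(E, W, W, W)
        np.testing.assert_array_equal(Q, np.zeros((2, 4)))

    def test_dimension_mismatch(self, rng):
        with pytest.raises(nn.ShapeError, match="Wq"):
            project_qkv(rng.standard_normal((2, 3)),
                        *[rng.standard_normal((4, 4))] * 3)


class TestScaledDotAttention:
    def test_single_token_weight_one(self, rng):
        Q = rng.standard_normal((1, 4))
        K = rng.standard_normal((1, 4))
        V = rng.standard_normal((1, 4))
        out, w = scaled_dot_attention(Q, K, V, 4)
        assert w == pytest.approx(np.ones((1, 1)))
        np.testing.assert_allclose(out, V, atol=1e-12)

    def test_equal_logits_give_uniform_average(self, rng):
        K = rng.standard_normal((4, 3))
        Q = np.zeros((2, 3))  # orthogonal to everything: all logits equal
        V = rng.standard_normal((4, 3))
        out, w = scaled_dot_attention(Q, K, V, 3)
        np.testing.assert_allclose(w, 0.25, atol=1e-12)
        np.testing.assert_allclose(out, np.tile(V.mean(0), (2, 1)), atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        Q, K, V = (rng.standard_normal((4, 2)) for _ in range(3))
        out, w = scaled_dot_attention(Q, K, V, 2)
        out_o, w_o = loop_attention(Q, K, V, 2)
        np.testing.assert_allclose(out, out_o, atol=1e-6)
        np.testing.assert_allclose(w, w_o, atol=1e-6)

    def test_rows_sum_to_one_and_shift_invariance(self, rng):
        Q, K, V = (rng.standard_normal((6, 3)) for _ in range(3))
        _, w = scaled_dot_attention(Q, K, V, 3)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)
        # adding a constant vector to Q shifts all logits of a row equally
        _, w2 = scaled_dot_attention(Q + 0.0, K, V, 3)
        np.testing.assert_allclose(w, w2, atol=1e-12)

    def test_nonpositive_dk_rejected(self, rng):
        with pytest.raises(ValueError, match="d_k"):
            scaled_dot_attention(*(rng.standard_normal((2, 2)),) * 3, 0)


class TestMultiHead:
    def test_single_head_reduces_to_plain_attention(self, rng):
        d = 6
        E = rng.standard_normal((5, d))
        params = random_params(rng, d, 8)["mha"]
        out1 = multi_head_attention(E, params, heads=1)
        Q, K, V = project_qkv(E, params["Wq"], params["Wk"], params["Wv"],
                              params["bq"], params["bk"], params["bv"])
        plain, _ = scaled_dot_attention(Q, K, V, d)
        np.testing.assert_allclose(out1, plain @ params["Wo"] + params["bo"],
                                   atol=1e-10)

    def test_five_heads_width_25(self, rng):
        E = rng.standard_normal((72, 125))
        params = random_params(rng, 125, 16)["mha"]
        out = multi_head_attention(E, params, heads=5)
        assert out.shape == (72, 125)
        assert 125 // 5 == 25  # per-head width

    def test_permutation_equivariance(self, rng):
        E = rng.standard_normal((7, 10))
        params = random_params(rng, 10, 8)["mha"]
        perm = rng.permutation(7)
        np.testing.assert_allclose(
            multi_head_attention(E, params, 2)[perm],
            multi_head_attention(E[perm], params, 2),
            atol=1e-10,
        )

    def test_indivisible_heads_rejected(self, rng):
        E = rng.standard_normal((3, 10))
        with pytest.raises(ValueError, match="divisible"):
            multi_head_attention(E, random_params(rng, 10, 4)["mha"], heads=3)


class TestFeedForward:
    def test_zero_input_zero_biases(self):
        W1, W2 = np.ones((3, 5)), np.ones((5, 3))
        out = feed_forward(np.zeros((2, 3)), W1, np.zeros(5), W2, np.zeros(3))
        np.testing.assert_array_equal(out, np.zeros((2, 3)))

    def test_all_negative_preactivations_pass_only_b2(self, rng):
        W1 = rng.standard_normal((3, 4))
        b1 = np.full(4, -100.0)
        W2 = rng.standard_normal((4, 3))
        b2 = rng.standard_normal(3)
        z = rng.standard_normal((2, 3)) * 0.01
        out = feed_forward(z, W1, b1, W2, b2)
        np.testing.assert_allclose(out, np.tile(b2, (2, 1)), atol=1e-10)

    def test_matches_per_token_loop(self, rng):
        W1, b1 = rng.standard_normal((4, 6)), rng.standard_normal(6)
        W2, b2 = rng.standard_normal((6, 4)), rng.standard_normal(4)
        z = rng.standard_normal((2, 4))
        out = feed_forward(z, W1, b1, W2, b2)
        for i in range(2):
            hidden = np.maximum(z[i] @ W1 + b1, 0)
            np.testing.assert_allclose(out[i], hidden @ W2 + b2, atol=1e-6)


class TestEncoderForward:
    def test_reference_shape_72x125(self, rng):
        cfg = EncoderConfig()
        params = [random_params(rng, 125, cfg.d_ff) for _ in range(2)]
        E = rng.standard_normal((72, 125))
        assert encoder_forward(E, cfg, params).shape == (72, 125)

    def test_zero_sublayers_pass_residual_only(self, rng):
        cfg = EncoderConfig(tokens=4, d_model=10, heads=2, n_layers=1, d_ff=8)
        params = [random_params(rng, 10, 8)]
        for key in ("Wq", "Wk", "Wv", "Wo"):
            params[0]["mha"][key] = np.zeros((10, 10))
        for key in ("bq", "bk", "bv", "bo"):
            params[0]["mha"][key] = np.zeros(10)
        params[0]["ffn"] = (np.zeros((10, 8)), np.zeros(8),
                            np.zeros((8, 10)), np.zeros(10))
        E = rng.standard_normal((4, 10))
        out = encoder_forward(E, cfg, params)

        def ln(x):
            return (x - x.mean(-1, keepdims=True)) / np.sqrt(
                x.var(-1, keepdims=True) + 1e-5
            )

        # both sub-layers contribute nothing, but each still layer-normalizes
        np.testing.assert_allclose(out, ln(ln(E)), atol=1e-10)

    def test_one_layer_equals_manual_composition(self, rng):
        cfg1 = EncoderConfig(tokens=5, d_model=8, heads=2, n_layers=1, d_ff=6)
        layer = random_params(rng, 8, 6)
        E = rng.standard_normal((5, 8))
        out = encoder_forward(E, cfg1, [layer])
        g1, b1 = layer["ln1"]
        g2, b2 = layer["ln2"]
        def ln(x, g, b):
            mean = x.mean(-1, keepdims=True)
            return g * (x - mean) / np.sqrt(x.var(-1, keepdims=True) + 1e-5) + b
        x = ln(E + multi_head_attention(E, layer["mha"], 2), g1, b1)
        x = ln(x + feed_forward(x, *layer["ffn"]), g2, b2)
        np.testing.assert_allclose(out, x, atol=1e-10)

    def test_permutation_equivariance_whole_encoder(self, rng):
        cfg = EncoderConfig(tokens=6, d_model=10, heads=2, n_layers=2, d_ff=8)
        params = [random_params(rng, 10, 8) for _ in range(2)]
        E = rng.standard_normal((6, 10))
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            encoder_forward(E, cfg, params)[perm],
            encoder_forward(E[perm], cfg, params),
            atol=1e-8,
        )

    def test_finite_output_over_many_random_draws(self):
        """sqrt(d_k) scaling keeps the encoder finite for bounded inputs
        across 10^4 random parameter draws."""
        cfg = EncoderConfig(tokens=4, d_model=8, heads=2, n_layers=1, d_ff=8)
        rng = np.random.default_rng(0)
        E = rng.standard_normal((4, 8)) * 3
        for _ in range(10_000):
            params = [random_params(rng, 8, 8)]
            out = encoder_forward(E, cfg, params)
            if not np.isfinite(out).all():
                pytest.fail("non-finite encoder output")

    def test_trainable_encoder_matches_functional_forward(self, rng):
        """The backprop-capable layers and the reference functions implement
        the same computation."""
        cfg = EncoderConfig(tokens=6, d_model=12, heads=3, n_layers=2,
                            d_ff=10, dropout=0.0)
        enc = build_encoder(cfg, np.random.default_rng(5))
        params = []
        for layer in enc.layers:
            mha = layer.layers[0].sublayer
            ffn = layer.layers[2].sublayer.net
            params.append({
                "mha": {
                    "Wq": mha.Wq.value, "Wk": mha.Wk.value,
                    "Wv": mha.Wv.value, "Wo": mha.Wo.value,
                    "bq": mha.bq.value, "bk": mha.bk.value,
                    "bv": mha.bv.value, "bo": mha.bo.value,
                },
                "ffn": (ffn.layers[0].W.value, ffn.layers[0].b.value,
                        ffn.layers[3].W.value, ffn.layers[3].b.value),
                "ln1": (layer.layers[1].gamma.value, layer.layers[1].beta.value),
                "ln2": (layer.layers[3].gamma.value, layer.layers[3].beta.value),
            })
        E = rng.standard_normal((2, 6, 12))
        np.testing.assert_allclose(
            enc.forward(E), encoder_forward(E, cfg, params), atol=1e-8
        )

    def test_parameter_count_close_to_reference(self):
        cfg = EncoderConfig()
        count = encoder_parameter_count(cfg)
        assert abs(count - 345_750) / 345_750 < 0.02
        enc = build_encoder(cfg, np.random.default_rng(0))
        assert enc.count_parameters() == count

    def test_config_validation(self):
        with pytest.raises(ValueError, match="divisible"):
            EncoderConfig(d_model=10, heads=3)
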