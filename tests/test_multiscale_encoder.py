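import math
from dataclasses import replace

import numpy as np
import pytest

from mscan.multiscale_encoder import (
    BRANCHES,
    ModelConfig,
    MSCANModel,
    Predictor,
    ScaleBundle,
    VARIANTS,
    build_variant,
    centered_window,
    classify,
    encoder_forward,
    extract_subsequences,
    ffn,
    layer_norm,
    msca_sublayer,
    positional_encoding,
    project_embedding,
    scaled_dot_attention,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def oracle_softmax_rows(scores):
    out = np.zeros_like(scores)
    for i in range(scores.shape[0]):
        row = scores[i]
        e = [math.exp(v - max(row)) for v in row]
        z = sum(e)
        out[i] = [v / z for v in e]
    return out


def oracle_attention(Q, K, V):
    m_q, d_k = Q.shape
    scores = np.zeros((m_q, K.shape[0]))
    for i in range(m_q):
        for j in range(K.shape[0]):
            scores[i, j] = float(Q[i] @ K[j]) / math.sqrt(d_k)
    w = oracle_softmax_rows(scores)
    out = np.zeros((m_q, V.shape[1]))
    for i in range(m_q):
        for j in range(K.shape[0]):
            out[i] += w[i, j] * V[j]
    return out, w


def oracle_msca(query, aux, params, variant, h):
    """Per-head, per-branch loops; sum branches, concat heads, project."""
    d_model = query.shape[1]
    d_k = d_model // h
    heads = []
    for i in range(h):
        sl = slice(i * d_k, (i + 1) * d_k)
        acc = np.zeros((query.shape[0], d_k))
        for branch in BRANCHES[variant]:
            src = query if branch == "self" else aux[int(branch[-1]) - 1]
            q = query @ params[f"{branch}_Wq"][:, sl]
            k = src @ params[f"{branch}_Wk"][:, sl]
            v = src @ params[f"{branch}_Wv"][:, sl]
            out, _ = oracle_attention(q, k, v)
            acc = acc + out
        heads.append(acc)
    return np.concatenate(heads, axis=1) @ params["Wo"]


def random_msca_params(rng, d_model, h, variant):
    p = {}
    for branch in BRANCHES[variant]:
        for role in ("Wq", "Wk", "Wv"):
            p[f"{branch}_{role}"] = rng.normal(size=(d_model, d_model))
    p["Wo"] = rng.normal(size=(d_model, d_model))
    return p


# ---------------------------------------------------------------------------
# subsequence extraction
# ---------------------------------------------------------------------------

class TestExtractSubsequences:
    def test_lengths(self):
        seq = "ACGU" * 10 + "A"
        s21, s31 = extract_subsequences(seq)
        assert (len(s21), len(s31)) == (21, 31)

    def test_exact_indices(self):
        seq = "".join(chr(ord("A") + i % 26) for i in range(41))
        s21, s31 = extract_subsequences(seq)
        assert s21 == seq[10:31]
        assert s31 == seq[5:36]

    def test_center_preserved(self):
        seq = "A" * 20 + "G" + "A" * 20
        s21, s31 = extract_subsequences(seq)
        assert s21[10] == "G"
        assert s31[15] == "G"
        assert s21[len(s21) // 2] == seq[20]
        assert s31[len(s31) // 2] == seq[20]

    def test_wrong_length_errors(self):
        with pytest.raises(ValueError):
            extract_subsequences("A" * 40)

    def test_centered_window_identity(self):
        seq = "ACGU" * 10 + "A"
        assert centered_window(seq, 41) == seq


# ---------------------------------------------------------------------------
# positional encoding
# ---------------------------------------------------------------------------

class TestPositionalEncoding:
    def test_position_zero(self):
        pe = positional_encoding(5, 8)
        np.testing.assert_allclose(pe[0, 0::2], 0.0)
        np.testing.assert_allclose(pe[0, 1::2], 1.0)

    def test_entry_1_0_is_sin_1(self):
        pe = positional_encoding(3, 4)
        assert pe[1, 0] == pytest.approx(math.sin(1.0), abs=1e-12)

    def test_bounded(self):
        pe = positional_encoding(50, 64)
        assert np.all(pe >= -1.0) and np.all(pe <= 1.0)

    def test_closed_form_oracle(self):
        m, d = 7, 10
        pe = positional_encoding(m, d)
        for pos in range(m):
            for i in range(d // 2):
                angle = pos / 10000 ** (2 * i / d)
                assert pe[pos, 2 * i] == pytest.approx(math.sin(angle), abs=1e-12)
                assert pe[pos, 2 * i + 1] == pytest.approx(math.cos(angle), abs=1e-12)

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(5, 7)


# ---------------------------------------------------------------------------
# projection / attention / ffn / classify
# ---------------------------------------------------------------------------

class TestProjection:
    def test_shape(self, rng):
        x = rng.normal(size=(39, 100))
        w = rng.normal(size=(100, 64))
        out = project_embedding(x, w, np.zeros(64))
        assert out.shape == (39, 64)

    def test_identity(self, rng):
        x = rng.normal(size=(5, 8))
        out = project_embedding(x, np.eye(8), np.zeros(8))
        np.testing.assert_array_equal(out, x)

    def test_zero_map(self, rng):
        x = rng.normal(size=(5, 8))
        out = project_embedding(x, np.zeros((8, 8)), np.zeros(8))
        np.testing.assert_array_equal(out, np.zeros((5, 8)))

    def test_width_mismatch(self, rng):
        with pytest.raises(ValueError):
            project_embedding(rng.normal(size=(5, 7)), np.zeros((8, 4)), np.zeros(4))


class TestScaledDotAttention:
    def test_single_source_row(self, rng):
        Q = rng.normal(size=(4, 3))
        K = rng.normal(size=(1, 3))
        V = rng.normal(size=(1, 5))
        out, w = scaled_dot_attention(Q, K, V)
        np.testing.assert_allclose(w, np.ones((4, 1)))
        np.testing.assert_allclose(out, np.repeat(V, 4, axis=0))

    def test_orthogonal_gives_uniform(self, rng):
        K = rng.normal(size=(6, 3))
        Q = np.zeros((2, 3))  # all scores zero
        V = rng.normal(size=(6, 4))
        out, w = scaled_dot_attention(Q, K, V)
        np.testing.assert_allclose(w, np.full((2, 6), 1 / 6))
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (2, 1)))

    def test_matches_oracle(self, rng):
        for _ in range(20):
            Q = rng.normal(size=(3, 2))
            K = rng.normal(size=(5, 2))
            V = rng.normal(size=(5, 4))
            out, w = scaled_dot_attention(Q, K, V)
            o_out, o_w = oracle_attention(Q, K, V)
            np.testing.assert_allclose(out, o_out, atol=1e-10)
            np.testing.assert_allclose(w, o_w, atol=1e-10)

    def test_rows_sum_to_one(self, rng):
        Q, K, V = (rng.normal(size=s) for s in ((7, 4), (9, 4), (9, 4)))
        _, w = scaled_dot_attention(Q, K, V)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)

    def test_nonfinite_rejected(self, rng):
        Q = rng.normal(size=(3, 2))
        Q[0, 0] = np.nan
        with pytest.raises(ValueError):
            scaled_dot_attention(Q, np.ones((2, 2)), np.ones((2, 2)))


class TestMscaSublayer:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_output_shape(self, rng, variant):
        d_model, h = 8, 2
        bundle = ScaleBundle(rng.normal(size=(5, d_model)),
                             (rng.normal(size=(7, d_model)),
                              rng.normal(size=(6, d_model))))
        params = random_msca_params(rng, d_model, h, variant)
        out = msca_sublayer(bundle, params, variant, h)
        assert out.shape == (5, d_model)

    def test_zero_values_give_zero(self, rng):
        d_model, h = 8, 2
        variant = "MSCAN"
        params = random_msca_params(rng, d_model, h, variant)
        for branch in BRANCHES[variant]:
            params[f"{branch}_Wv"] = np.zeros((d_model, d_model))
        bundle = ScaleBundle(rng.normal(size=(4, d_model)),
                             (rng.normal(size=(5, d_model)),
                              rng.normal(size=(6, d_model))))
        out = msca_sublayer(bundle, params, variant, h)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_matches_oracle(self, rng, variant):
        d_model, h = 8, 2
        for _ in range(10):
            query = rng.normal(size=(3, d_model))
            aux = (rng.normal(size=(4, d_model)), rng.normal(size=(5, d_model)))
            params = random_msca_params(rng, d_model, h, variant)
            out = msca_sublayer(ScaleBundle(query, aux), params, variant, h)
            expected = oracle_msca(query, aux, params, variant, h)
            np.testing.assert_allclose(out, expected, atol=1e-8)

    def test_unknown_variant(self, rng):
        bundle = ScaleBundle(rng.normal(size=(3, 4)))
        with pytest.raises(ValueError):
            msca_sublayer(bundle, {}, "XXX", 2)

    def test_cross_branch_kv_permutation_invariance(self, rng):
        """Jointly permuting an aux scale's rows leaves the output unchanged."""
        d_model, h = 8, 2
        query = rng.normal(size=(4, d_model))
        aux1 = rng.normal(size=(6, d_model))
        aux2 = rng.normal(size=(5, d_model))
        params = random_msca_params(rng, d_model, h, "MSCAN")
        base = msca_sublayer(ScaleBundle(query, (aux1, aux2)), params, "MSCAN", h)
        perm = rng.permutation(6)
        permuted = msca_sublayer(
            ScaleBundle(query, (aux1[perm], aux2)), params, "MSCAN", h
        )
        np.testing.assert_allclose(base, permuted, atol=1e-10)


class TestFfn:
    def test_identity_on_nonnegative(self, rng):
        x = np.abs(rng.normal(size=(3, 4)))
        out = ffn(x, np.eye(4), np.zeros(4), np.eye(4), np.zeros(4))
        np.testing.assert_allclose(out, x)

    def test_relu_kills_negative_inner(self, rng):
        x = rng.normal(size=(3, 4))
        W1 = np.zeros((4, 6))
        b1 = -np.ones(6)
        W2 = rng.normal(size=(6, 4))
        b2 = rng.normal(size=4)
        out = ffn(x, W1, b1, W2, b2)
        np.testing.assert_allclose(out, np.tile(b2, (3, 1)))

    def test_matches_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=(2, 4))
            W1, b1 = rng.normal(size=(4, 8)), rng.normal(size=8)
            W2, b2 = rng.normal(size=(8, 4)), rng.normal(size=4)
            expected = np.maximum(0.0, x @ W1 + b1) @ W2 + b2
            np.testing.assert_allclose(ffn(x, W1, b1, W2, b2), expected,
                                       atol=1e-10)


class TestClassify:
    def test_zero_weights_give_half(self, rng):
        enc = rng.normal(size=(5, 8))
        assert classify(enc, np.zeros(8), 0.0) == pytest.approx(0.5)

    def test_open_interval(self, rng):
        for _ in range(10):
            p = classify(rng.normal(size=(4, 6)) * 10, rng.normal(size=6), 0.0)
            assert 0.0 < p < 1.0

    def test_hand_computed(self):
        enc = np.array([[1.0, 2.0], [3.0, 4.0]])
        w = np.array([0.5, -1.0])
        b = 0.25
        z = 0.5 * 2.0 - 1.0 * 3.0 + 0.25
        assert classify(enc, w, b) == pytest.approx(1 / (1 + math.exp(-z)),
                                                    abs=1e-12)


def test_layer_norm_statistics(rng):
    x = rng.normal(size=(6, 32)) * 3 + 1
    out = layer_norm(x, np.ones(32), np.zeros(32))
    np.testing.assert_allclose(out.mean(axis=-1), 0.0, atol=1e-4)
    np.testing.assert_allclose(out.var(axis=-1), 1.0, atol=1e-3)


# ---------------------------------------------------------------------------
# config validation
# ---------------------------------------------------------------------------

TINY = dict(d_model=8, h=2, d_k=4, d_v=4, d_ff=16, layers=1, dropout=0.0,
            scale_order=(5, 9, 7), d_embed=6)


class TestModelConfig:
    def test_defaults(self):
        c = ModelConfig()
        assert (c.d_model, c.h, c.d_k, c.d_v, c.d_ff, c.layers) == \
            (64, 8, 8, 8, 256, 3)
        assert c.dropout == 0.2
        assert c.scale_order == (21, 41, 31)

    def test_head_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(d_model=64, h=8, d_k=16, d_v=16)

    def test_indivisible_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(d_model=60, h=8, d_k=7, d_v=7)

    def test_even_scale_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(scale_order=(20, 41, 31))

    def test_duplicate_scales_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(scale_order=(21, 21, 31))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(variant="FOO")

    def test_streams(self):
        assert ModelConfig(variant="SAN").streams == (0,)
        assert ModelConfig(variant="SCAN").streams == (0, 1)
        assert ModelConfig(variant="CAN").streams == (0, 1)
        assert ModelConfig(variant="MSCAN").streams == (0, 1, 2)


# ---------------------------------------------------------------------------
# model-level behaviour
# ---------------------------------------------------------------------------

def tiny_bundles(rng, cfg, batch=2):
    return [rng.normal(size=(batch, s - 2, cfg.d_embed))
            for s in cfg.scale_order]


def expected_n_params(cfg: ModelConfig) -> int:
    n_streams = len(cfg.streams)
    n_branches = len(BRANCHES[cfg.variant])
    total = n_streams * (cfg.d_embed * cfg.d_model + cfg.d_model)
    per_layer = (
        n_branches * (2 * cfg.d_model * cfg.h * cfg.d_k
                      + cfg.d_model * cfg.h * cfg.d_v)
        + cfg.h * cfg.d_v * cfg.d_model
        + cfg.d_model * cfg.d_ff + cfg.d_ff
        + cfg.d_ff * cfg.d_model + cfg.d_model
        + 4 * cfg.d_model
    )
    total += cfg.layers * per_layer
    total += cfg.d_model + 1  # classifier
    return total


class TestModel:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_parameter_count_closed_form(self, variant):
        cfg = ModelConfig(variant=variant)
        model = MSCANModel(cfg, seed=0)
        assert model.n_parameters() == expected_n_params(cfg)

    def test_same_seed_bitwise_identical(self):
        cfg = ModelConfig(**TINY)
        a = MSCANModel(cfg, seed=3)
        b = MSCANModel(cfg, seed=3)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k].data, b.params[k].data)

    def test_different_seed_differs(self):
        cfg = ModelConfig(**TINY)
        a = MSCANModel(cfg, seed=3)
        b = MSCANModel(cfg, seed=4)
        assert any(
            not np.array_equal(a.params[k].data, b.params[k].data)
            for k in a.params
        )

    def test_san_ignores_aux(self, rng):
        cfg = ModelConfig(**TINY, variant="SAN")
        model = MSCANModel(cfg, seed=0)
        bundles = tiny_bundles(rng, cfg)
        base = model.predict_proba(bundles)
        perturbed = [bundles[0], bundles[1] + 100.0, bundles[2] - 50.0]
        np.testing.assert_array_equal(base, model.predict_proba(perturbed))

    def test_eval_mode_deterministic(self, rng):
        cfg = ModelConfig(**TINY)
        model = MSCANModel(cfg, seed=0)
        bundles = tiny_bundles(rng, cfg)
        np.testing.assert_array_equal(
            model.predict_proba(bundles), model.predict_proba(bundles)
        )

    def test_zero_layers_returns_projected_query(self, rng):
        cfg = ModelConfig(**{**TINY, "layers": 0})
        model = MSCANModel(cfg, seed=0)
        bundles = tiny_bundles(rng, cfg)
        out = encoder_forward(model, bundles)
        w = model.params["proj0_W"].data
        b = model.params["proj0_b"].data
        expected = bundles[0] @ w + b + positional_encoding(
            cfg.scale_order[0] - 2, cfg.d_model
        )
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_probabilities_in_unit_interval(self, rng):
        cfg = ModelConfig(**TINY)
        model = MSCANModel(cfg, seed=1)
        p = model.predict_proba(tiny_bundles(rng, cfg, batch=5))
        assert p.shape == (5,)
        assert np.all((p > 0) & (p < 1))

    def test_encoded_layernorm_statistics(self, rng):
        # pre-affine LayerNorm output has ~zero mean / unit variance per row;
        # with identity gamma/beta the encoder output inherits them
        cfg = ModelConfig(**TINY)
        model = MSCANModel(cfg, seed=2)
        out = model.encode(tiny_bundles(rng, cfg))
        np.testing.assert_allclose(out.mean(axis=-1), 0.0, atol=1e-4)
        np.testing.assert_allclose(out.var(axis=-1), 1.0, atol=1e-3)

    def test_build_variant_rejects_unknown(self):
        with pytest.raises(ValueError):
            build_variant("XXXX", ModelConfig(), seed=0)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cfg = ModelConfig(**TINY)
        model = MSCANModel(cfg, seed=0)
        bundles = tiny_bundles(rng, cfg)
        before = model.predict_proba(bundles)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = MSCANModel.load(path)
        assert loaded.config == cfg
        np.testing.assert_array_equal(loaded.predict_proba(bundles), before)
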