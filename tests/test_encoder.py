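"""Tokenization, divided attention and block structure of the encoder."""

import numpy as np
import pytest

from histo25d.encoder import (
    AttentionMaps,
    DepthEncoder,
    EncoderConfig,
    count_parameters,
    encoder_block,
    init_encoder_params,
    layer_norm,
    qkv_project,
    space_attention,
    time_attention,
    tokenize,
    _stage_weights,
)

CFG_SMALL = EncoderConfig(patch_px=16, embed_dim=8, n_heads=2, n_layers=1,
                          input_px=32, n_slices=2, seed=0)


class TestConfig:
    def test_token_counting(self):
        assert CFG_SMALL.n_patches == 4
        assert CFG_SMALL.n_tokens == 4 * 2 + 1

    def test_embed_dim_divisibility_enforced(self):
        with pytest.raises(ValueError):
            EncoderConfig(embed_dim=10, n_heads=4)

    def test_parameter_count_is_config_function(self):
        cfg = EncoderConfig()   # P=8, D=64, A=4, L=2, input 32, F=4
        d, p = 64, 8
        n, f = cfg.n_patches, cfg.n_slices
        per_stage = 2 * d + 3 * (d * d + d) + d * d + d       # ln + qkv + proj
        per_layer = 2 * per_stage + (2 * d + 256 * d + 256 + d * 256 + d)
        expected = (d * 3 * p * p + d) + d + n * f * d + 2 * per_layer + 2 * d
        assert count_parameters(cfg) == expected


class TestTokenize:
    def test_token_count(self):
        patch = np.zeros((2, 32, 32, 3))
        tokens = tokenize(patch, CFG_SMALL, init_encoder_params(CFG_SMALL))
        assert tokens.shape == (9, 8)

    def test_zero_input_zero_tables_give_zero_patch_tokens(self):
        params = init_encoder_params(CFG_SMALL)
        params["pos"] = np.zeros_like(params["pos"])
        # pixel value 0.5 maps to the embedding's zero point
        patch = np.full((2, 32, 32, 3), 0.5)
        tokens = tokenize(patch, CFG_SMALL, params)
        np.testing.assert_allclose(tokens[1:], 0.0, atol=1e-12)

    def test_spot_checked_tokens_match_manual_linear_algebra(self, rng):
        params = init_encoder_params(CFG_SMALL)
        patch = rng.random((2, 32, 32, 3))
        tokens = tokenize(patch, CFG_SMALL, params)
        p = CFG_SMALL.patch_px
        for (pi, ti) in [(0, 0), (3, 1), (2, 0)]:
            py, px = divmod(pi, 2)   # 2x2 tile grid
            tile = patch[ti, py * p:(py + 1) * p, px * p:(px + 1) * p] - 0.5
            expected = (params["embed_W"] @ tile.ravel() + params["embed_b"]
                        + params["pos"][pi, ti])
            np.testing.assert_allclose(tokens[1 + ti * 4 + pi], expected,
                                       atol=1e-12)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            tokenize(np.zeros((2, 33, 33, 3)), CFG_SMALL,
                     init_encoder_params(CFG_SMALL))


class TestQKV:
    def test_standardized_rows_are_layernorm_fixed_points(self, rng):
        x = rng.normal(size=(6, 8))
        x = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        out = layer_norm(x, np.ones(8), np.zeros(8))
        np.testing.assert_allclose(out, x, atol=1e-5)

    def test_zero_weights_give_zero_projections(self, rng):
        lw = {"ln_g": np.ones(8), "ln_b": np.zeros(8),
              "Wq": np.zeros((8, 8)), "bq": np.zeros(8),
              "Wk": np.zeros((8, 8)), "bk": np.zeros(8),
              "Wv": np.zeros((8, 8)), "bv": np.zeros(8), "n_heads": 2}
        q, k, v = qkv_project(rng.normal(size=(5, 8)), lw, n_heads=2)
        assert not q.any() and not k.any() and not v.any()

    def test_matches_independent_dense_layer(self, rng):
        params = init_encoder_params(CFG_SMALL)
        lw = _stage_weights(params, 0, "time", 2)
        tokens = rng.normal(size=(9, 8))
        q, k, v = qkv_project(tokens, lw, n_heads=2)
        # independent: explicit normalization + matrix product, head 1 slice
        mu = tokens.mean(1, keepdims=True)
        sd = np.sqrt(tokens.var(1, keepdims=True) + 1e-6)
        h = (tokens - mu) / sd
        q_manual = h @ lw["Wq"].T + lw["bq"]
        np.testing.assert_allclose(q[1], q_manual[:, 4:], atol=1e-10)
        v_manual = h @ lw["Wv"].T + lw["bv"]
        np.testing.assert_allclose(v[0], v_manual[:, :4], atol=1e-10)


class TestDividedAttention:
    def _zero_qk_params(self):
        params = init_encoder_params(CFG_SMALL)
        for stage in ("time", "space"):
            params[f"l0_{stage}_Wq"] = np.zeros((8, 8))
            params[f"l0_{stage}_bq"] = np.zeros(8)
            params[f"l0_{stage}_Wk"] = np.zeros((8, 8))
            params[f"l0_{stage}_bk"] = np.zeros(8)
        return params

    def test_zero_logits_give_uniform_time_weights(self, rng):
        params = self._zero_qk_params()
        tokens = rng.normal(size=(9, 8))
        maps = AttentionMaps()
        time_attention(tokens, CFG_SMALL, _stage_weights(params, 0, "time", 2), maps)
        f = CFG_SMALL.n_slices
        np.testing.assert_allclose(maps.time[0], 1.0 / (f + 1), atol=1e-12)

    def test_zero_logits_give_uniform_space_weights(self, rng):
        params = self._zero_qk_params()
        tokens = rng.normal(size=(9, 8))
        maps = AttentionMaps()
        space_attention(tokens, CFG_SMALL, _stage_weights(params, 0, "space", 2), maps)
        n = CFG_SMALL.n_patches
        np.testing.assert_allclose(maps.space[0], 1.0 / (n + 1), atol=1e-12)

    def test_all_rows_sum_to_one(self, rng):
        cfg = EncoderConfig(patch_px=8, embed_dim=16, n_heads=4, n_layers=2,
                            input_px=24, n_slices=3, seed=2)
        enc = DepthEncoder(cfg)
        _, maps = enc.forward(rng.random((3, 24, 24, 3)), record_attention=True)
        for layer in range(2):
            np.testing.assert_allclose(maps.time[layer].sum(-1), 1.0, atol=1e-6)
            np.testing.assert_allclose(maps.space[layer].sum(-1), 1.0, atol=1e-6)
            np.testing.assert_allclose(maps.cls_space[layer].sum(-1), 1.0, atol=1e-6)

    def test_cls_token_unchanged_by_time_attention(self, rng):
        params = init_encoder_params(CFG_SMALL)
        tokens = rng.normal(size=(9, 8))
        out = time_attention(tokens, CFG_SMALL,
                             _stage_weights(params, 0, "time", 2))
        np.testing.assert_array_equal(out[0], tokens[0])
        assert not np.allclose(out[1:], tokens[1:])


class TestBlock:
    def test_shape_invariant_over_blocks(self, rng):
        cfg = EncoderConfig(patch_px=16, embed_dim=8, n_heads=2, n_layers=3,
                            input_px=32, n_slices=2, seed=1)
        enc = DepthEncoder(cfg)
        tokens, _ = enc.forward(rng.random((2, 32, 32, 3)))
        assert tokens.shape == (9, 8)

    def test_zeroed_outputs_make_identity_block(self, rng):
        params = init_encoder_params(CFG_SMALL)
        for stage in ("time", "space"):
            params[f"l0_{stage}_Wo"] = np.zeros((8, 8))
            params[f"l0_{stage}_bo"] = np.zeros(8)
        params["l0_mlp_W2"] = np.zeros((8, 32))
        params["l0_mlp_b2"] = np.zeros(8)
        tokens = rng.normal(size=(9, 8))
        out = encoder_block(tokens, CFG_SMALL, params, 0)
        np.testing.assert_allclose(out, tokens, atol=1e-12)

    def test_block_equals_hand_chained_stages(self, rng):
        from histo25d.encoder import gelu
        params = init_encoder_params(CFG_SMALL)
        tokens = rng.normal(size=(9, 8))
        out = encoder_block(tokens, CFG_SMALL, params, 0)
        z = time_attention(tokens, CFG_SMALL, _stage_weights(params, 0, "time", 2))
        z = space_attention(z, CFG_SMALL, _stage_weights(params, 0, "space", 2))
        h = layer_norm(z, params["l0_mlp_ln_g"], params["l0_mlp_ln_b"])
        h = gelu(h @ params["l0_mlp_W1"].T + params["l0_mlp_b1"])
        manual = z + h @ params["l0_mlp_W2"].T + params["l0_mlp_b2"]
        np.testing.assert_array_equal(out, manual)

    def test_depth_permutation_equivariance(self, rng):
        cfg = EncoderConfig(patch_px=8, embed_dim=16, n_heads=2, n_layers=2,
                            input_px=16, n_slices=4, seed=3)
        n, f = cfg.n_patches, cfg.n_slices
        patch = rng.random((f, 16, 16, 3))
        perm = np.array([2, 0, 3, 1])
        enc = DepthEncoder(cfg)
        params_p = {k: v.copy() for k, v in enc.params.items()}
        params_p["pos"] = params_p["pos"][:, perm]
        out, _ = enc.forward(patch)
        out_p, _ = DepthEncoder(cfg, params_p).forward(patch[perm])
        np.testing.assert_allclose(out_p[0], out[0], atol=1e-9)
        for t in range(f):
            for p in range(n):
                np.testing.assert_allclose(out_p[1 + t * n + p],
                                           out[1 + perm[t] * n + p], atol=1e-9)
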