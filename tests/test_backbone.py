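"""Dual-branch transformer: shape contracts, loop-based oracles, training."""

import numpy as np
import pytest

import histofuse.autodiff as ad
import histofuse.backbone as bb
from histofuse.backbone import (BackboneConfig, DeepFeatures, TINY,
                                cross_attention_fuse, embed_patches,
                                encoder_layer, forward_features, fuse_logits,
                                init_params, load_pretrained, save_params)
from histofuse.synthetic import generate_preset_dataset

MICRO = BackboneConfig(image_size=16, patch_small=4, patch_large=8,
                       dim_small=8, dim_large=16, depth=1, heads=2,
                       mlp_ratio=2.0, n_cross_rounds=1)

RNG = np.random.default_rng(123)


# ---------------------------------------------------------------------------
# independent loop-based reference implementation
# ---------------------------------------------------------------------------

def ref_layer_norm(x, g, b, eps=1e-6):
    mu = x.mean(axis=-1, keepdims=True)
    sd = np.sqrt(x.var(axis=-1, keepdims=True) + eps)
    return g * (x - mu) / sd + b


def ref_attention(q_in, kv_in, heads, wq, bq, wk, bk, wv, bv, wo=None, bo=None):
    """Explicit per-head, per-token scaled dot-product attention."""
    Tq, D = q_in.shape
    Tk = kv_in.shape[0]
    dk = D // heads
    q = q_in @ wq + bq
    k = kv_in @ wk + bk
    v = kv_in @ wv + bv
    out = np.zeros((Tq, D))
    for h in range(heads):
        sl = slice(h * dk, (h + 1) * dk)
        for t in range(Tq):
            scores = np.array([q[t, sl] @ k[u, sl] for u in range(Tk)]) / np.sqrt(dk)
            e = np.exp(scores - scores.max())
            a = e / e.sum()
            for u in range(Tk):
                out[t, sl] += a[u] * v[u, sl]
    if wo is not None:
        out = out @ wo + bo
    return out


def ref_encoder_layer(x, p, prefix, heads):
    u = ref_layer_norm(x, p[f"{prefix}.ln1.g"].data, p[f"{prefix}.ln1.b"].data)
    msa = ref_attention(u, u, heads,
                        p[f"{prefix}.attn.wq"].data, p[f"{prefix}.attn.bq"].data,
                        p[f"{prefix}.attn.wk"].data, p[f"{prefix}.attn.bk"].data,
                        p[f"{prefix}.attn.wv"].data, p[f"{prefix}.attn.bv"].data,
                        p[f"{prefix}.attn.wo"].data, p[f"{prefix}.attn.bo"].data)
    y = x + msa
    v = ref_layer_norm(y, p[f"{prefix}.ln2.g"].data, p[f"{prefix}.ln2.b"].data)
    h = v @ p[f"{prefix}.ffn.w1"].data + p[f"{prefix}.ffn.b1"].data
    from scipy.special import erf
    h = h * 0.5 * (1 + erf(h / np.sqrt(2)))
    return y + h @ p[f"{prefix}.ffn.w2"].data + p[f"{prefix}.ffn.b2"].data


def ref_cross_fuse(cls_src, patches_other, p, prefix, heads):
    h = cls_src @ p[f"{prefix}.f.w"].data + p[f"{prefix}.f.b"].data
    x = np.concatenate([h, patches_other], axis=0) if len(patches_other) else h
    u = ref_layer_norm(x, p[f"{prefix}.ln.g"].data, p[f"{prefix}.ln.b"].data)
    out = ref_attention(u[0:1], u, heads,
                        p[f"{prefix}.wq"].data, p[f"{prefix}.bq"].data,
                        p[f"{prefix}.wk"].data, p[f"{prefix}.bk"].data,
                        p[f"{prefix}.wv"].data, p[f"{prefix}.bv"].data)
    z = h + out
    return z @ p[f"{prefix}.g.w"].data + p[f"{prefix}.g.b"].data


def ref_forward(image_u8, config, p):
    """Full dual-branch forward pass written with explicit loops."""
    x = (image_u8.astype(np.float64) / 255.0 - 0.5) / 0.5
    states = {}
    for branch, patch, dim in (("small", config.patch_small, config.dim_small),
                               ("large", config.patch_large, config.dim_large)):
        n_side = config.image_size // patch
        tokens = []
        for gy in range(n_side):
            for gx in range(n_side):
                flat = x[gy * patch:(gy + 1) * patch,
                         gx * patch:(gx + 1) * patch, :].reshape(-1)
                tokens.append(flat @ p[f"{branch}.embed.w"].data
                              + p[f"{branch}.embed.b"].data)
        seq = np.vstack([p[f"{branch}.cls"].data[0, 0]] + tokens)
        seq = seq + p[f"{branch}.pos"].data[0]
        for k in range(config.depth):
            seq = ref_encoder_layer(seq, p, f"{branch}.enc{k}", config.heads)
        states[branch] = seq
    for r in range(config.n_cross_rounds):
        new_l = ref_cross_fuse(states["large"][0:1], states["small"][1:], p,
                               f"cross{r}.large", config.heads)
        new_s = ref_cross_fuse(states["small"][0:1], states["large"][1:], p,
                               f"cross{r}.small", config.heads)
        states["large"] = np.vstack([new_l, states["large"][1:]])
        states["small"] = np.vstack([new_s, states["small"][1:]])
    z_s = ref_layer_norm(states["small"][0], p["small.norm.g"].data,
                         p["small.norm.b"].data)
    z_l = ref_layer_norm(states["large"][0], p["large.norm.g"].data,
                         p["large.norm.b"].data)
    return z_s, z_l


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestConfig:
    def test_non_divisible_image_rejected(self):
        with pytest.raises(ValueError):
            BackboneConfig(image_size=64, patch_small=12)

    def test_dim_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            BackboneConfig(dim_small=30, heads=4)


class TestEmbedPatches:
    def test_token_count_224_patch16(self):
        config = BackboneConfig(image_size=224, patch_small=16, patch_large=32,
                                dim_small=8, dim_large=8, heads=2)
        params = init_params(config, 0)
        img = np.zeros((224, 224, 3), dtype=np.uint8)
        x = embed_patches(bb.normalize_images(img), 16, params, "small")
        assert x.shape == (1, 197, 8)  # (224/16)^2 + CLS

    def test_zero_maps_reduce_to_positional_encoding(self):
        params = init_params(MICRO, 0)
        for name in ("small.embed.w", "small.embed.b", "small.cls"):
            params[name].data[:] = 0.0
        img = np.full((16, 16, 3), 127, dtype=np.uint8)
        x = embed_patches(bb.normalize_images(img) * 0.0, 4, params, "small")
        np.testing.assert_allclose(x.data[0], params["small.pos"].data[0])

    def test_non_divisible_patch_rejected(self):
        with pytest.raises(ValueError):
            bb.patchify(np.zeros((1, 64, 64, 3)), 12)


class TestEncoderLayer:
    def test_pure_residual_when_value_and_ffn_zero(self):
        params = init_params(MICRO, 1)
        for name in ("small.enc0.attn.wv", "small.enc0.attn.bv",
                     "small.enc0.attn.bo", "small.enc0.ffn.w2",
                     "small.enc0.ffn.b2"):
            params[name].data[:] = 0.0
        x = ad.Tensor(RNG.normal(size=(1, 5, 8)))
        out = encoder_layer(x, params, "small.enc0", MICRO.heads)
        np.testing.assert_allclose(out.data, x.data, atol=1e-12)

    def test_attention_rows_are_probability_vectors(self):
        params = init_params(MICRO, 2)
        x = ad.Tensor(RNG.normal(size=(2, 5, 8)))
        _, attn = encoder_layer(x, params, "small.enc0", MICRO.heads,
                                return_attn=True)
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)
        assert (attn >= 0).all()

    def test_matches_loop_oracle_three_tokens_one_head(self):
        config = BackboneConfig(image_size=16, patch_small=4, patch_large=8,
                                dim_small=4, dim_large=8, depth=1, heads=1)
        params = init_params(config, 3)
        x0 = RNG.normal(size=(3, 4))
        out = encoder_layer(ad.Tensor(x0[None]), params, "small.enc0", 1)
        ref = ref_encoder_layer(x0, params, "small.enc0", 1)
        np.testing.assert_allclose(out.data[0], ref, atol=1e-6)

    def test_dimension_mismatch_rejected(self):
        params = init_params(MICRO, 0)
        with pytest.raises(ValueError):
            encoder_layer(ad.Tensor(np.zeros((1, 5, 16))), params,
                          "small.enc0", MICRO.heads)


class TestCrossAttention:
    def test_empty_patch_sequence_single_position_softmax(self):
        params = init_params(MICRO, 4)
        prefix = "cross0.large"
        # identity back-projection isolates the projected-space update
        params[f"{prefix}.g.w"].data = np.eye(8, 16)
        params[f"{prefix}.g.b"].data[:] = 0.0
        cls = ad.Tensor(RNG.normal(size=(1, 1, 16)))
        patches = ad.Tensor(np.zeros((1, 0, 8)))
        out, attn = cross_attention_fuse(cls, patches, params, prefix,
                                         heads=1, return_attn=True)
        np.testing.assert_allclose(attn, 1.0)
        p = params
        h = cls.data[0] @ p[f"{prefix}.f.w"].data + p[f"{prefix}.f.b"].data
        u = ref_layer_norm(h, p[f"{prefix}.ln.g"].data, p[f"{prefix}.ln.b"].data)
        expected = h + (u @ p[f"{prefix}.wv"].data + p[f"{prefix}.bv"].data)
        # with g = eye(8, 16) the first 8 output components are the projected-
        # space residual update and the rest are zero
        np.testing.assert_allclose(out.data[0][:, :8], expected, atol=1e-10)
        np.testing.assert_allclose(out.data[0][:, 8:], 0.0, atol=1e-12)

    def test_attention_distribution_sums_to_one(self):
        params = init_params(MICRO, 5)
        cls = ad.Tensor(RNG.normal(size=(2, 1, 16)))
        patches = ad.Tensor(RNG.normal(size=(2, 7, 8)))
        _, attn = cross_attention_fuse(cls, patches, params, "cross0.large",
                                       heads=2, return_attn=True)
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_matches_hand_coded_oracle_two_patches(self):
        params = init_params(MICRO, 6)
        cls0 = RNG.normal(size=(1, 16))
        patches0 = RNG.normal(size=(2, 8))
        out = cross_attention_fuse(ad.Tensor(cls0[None]),
                                   ad.Tensor(patches0[None]), params,
                                   "cross0.large", heads=1)
        ref = ref_cross_fuse(cls0, patches0, params, "cross0.large", 1)
        np.testing.assert_allclose(out.data[0], ref, atol=1e-6)

    def test_dimension_mismatch_rejected(self):
        params = init_params(MICRO, 0)
        with pytest.raises(ValueError):
            cross_attention_fuse(ad.Tensor(np.zeros((1, 1, 8))),
                                 ad.Tensor(np.zeros((1, 2, 8))),
                                 params, "cross0.large")


class TestForwardFeatures:
    def test_tiny_preset_dims(self):
        params = init_params(TINY, 0)
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        feats = forward_features(img, TINY, params)
        assert feats.z_cls_small.shape == (32,)
        assert feats.z_cls_large.shape == (64,)

    def test_deterministic_for_identical_images(self, small_image):
        params = init_params(TINY, 1)
        a = forward_features(small_image, TINY, params)
        b = forward_features(small_image.copy(), TINY, params)
        np.testing.assert_array_equal(a.z_cls_small, b.z_cls_small)
        np.testing.assert_array_equal(a.z_cls_large, b.z_cls_large)

    def test_full_forward_matches_loop_reference(self):
        params = init_params(MICRO, 7)
        img = np.random.default_rng(8).integers(0, 256, (16, 16, 3),
                                                dtype=np.uint8)
        feats = forward_features(img, MICRO, params)
        z_s, z_l = ref_forward(img, MICRO, params)
        np.testing.assert_allclose(feats.z_cls_small, z_s, atol=1e-5)
        np.testing.assert_allclose(feats.z_cls_large, z_l, atol=1e-5)


class TestFuseLogits:
    def test_identity_heads_mean(self):
        feats = DeepFeatures(z_cls_small=np.array([3.0, 1.0]),
                             z_cls_large=np.array([1.0, 3.0]))
        pair = fuse_logits(feats, (np.eye(2), np.zeros(2)),
                           (np.eye(2), np.zeros(2)))
        np.testing.assert_allclose(pair.logits_small, [3.0, 1.0])
        np.testing.assert_allclose(pair.logits_large, [1.0, 3.0])
        np.testing.assert_allclose(pair.fused, [2.0, 2.0])

    def test_equal_branch_outputs_pass_through(self):
        feats = DeepFeatures(z_cls_small=np.array([1.0, 2.0]),
                             z_cls_large=np.array([1.0, 2.0]))
        pair = fuse_logits(feats, (np.eye(2), np.zeros(2)),
                           (np.eye(2), np.zeros(2)))
        np.testing.assert_allclose(pair.fused, [1.0, 2.0])

    def test_matches_direct_formula(self):
        z_s, z_l = RNG.normal(size=5), RNG.normal(size=9)
        w_s, b_s = RNG.normal(size=(5, 2)), RNG.normal(size=2)
        w_l, b_l = RNG.normal(size=(9, 2)), RNG.normal(size=2)
        pair = fuse_logits(DeepFeatures(z_s, z_l), (w_s, b_s), (w_l, b_l))
        expected = 0.5 * (w_l.T @ z_l + b_l + w_s.T @ z_s + b_s)
        np.testing.assert_allclose(pair.fused, expected, atol=1e-7)

    def test_head_shape_mismatch_rejected(self):
        feats = DeepFeatures(z_cls_small=np.zeros(4), z_cls_large=np.zeros(8))
        with pytest.raises(ValueError):
            fuse_logits(feats, (np.eye(3), np.zeros(3)), (np.eye(8, 2), np.zeros(2)))


def test_training_halves_loss_on_one_batch():
    """200 optimiser steps on a fixed synthetic batch cut the fused-logit
    cross-entropy by at least half (gradient flow through every block)."""
    ds = generate_preset_dataset("easy", 4, (64, 64), 0)
    params = init_params(TINY, 0)
    images = np.stack(ds.images)
    losses = bb.train_backbone(images, ds.labels, TINY, params,
                               steps=200, batch_size=8, lr=1e-3, seed=0)
    assert losses[-1] <= 0.5 * losses[0]


class TestWeightArchive:
    def test_round_trip_all_tensors_matched(self, tmp_path):
        params = init_params(MICRO, 9)
        save_params(params, tmp_path / "w.npz")
        fresh = init_params(MICRO, 10)
        report = load_pretrained(fresh, tmp_path / "w.npz")
        assert not report.unmatched_archive and not report.unmatched_model
        assert sorted(report.matched) == sorted(params)
        np.testing.assert_array_equal(fresh["small.embed.w"].data,
                                      params["small.embed.w"].data)

    def test_renamed_tensor_reported_unmatched(self, tmp_path):
        params = init_params(MICRO, 9)
        arrays = {k: v.data for k, v in params.items()}
        arrays["small.embed.weight_renamed"] = arrays.pop("small.embed.w")
        np.savez(tmp_path / "w.npz", **arrays)
        fresh = init_params(MICRO, 10)
        report = load_pretrained(fresh, tmp_path / "w.npz")
        assert report.unmatched_archive == ["small.embed.weight_renamed"]
        assert report.unmatched_model == ["small.embed.w"]

    def test_shape_conflict_names_tensor(self, tmp_path):
        params = init_params(MICRO, 9)
        arrays = {k: v.data for k, v in params.items()}
        arrays["small.embed.w"] = np.zeros((2, 2))
        np.savez(tmp_path / "w.npz", **arrays)
        fresh = init_params(MICRO, 10)
        with pytest.raises(ValueError, match="small.embed.w"):
            load_pretrained(fresh, tmp_path / "w.npz")
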