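"""Operator-level behavior: pooling mixer, attention, SE, blocks,
patch embedding and merging."""

import numpy as np
import pytest

from metaswin.autograd import Tensor
from metaswin.blocks import (FeatureMap, MetaSwinBlock, PatchEmbed, PatchMerging,
                             PoolingMixer, PoolingSpec, SEBlock, SEConfig,
                             WindowAttention, average_pool_mixer, se_recalibrate)

RNG = np.random.default_rng(11)


def pooled_by_nested_loops(x: np.ndarray, k: int) -> np.ndarray:
    """Independent oracle: literal nested-loop neighborhood average.

    For each voxel, sum T[:, i+p-(K+1)/2, j+q-(K+1)/2, k+r-(K+1)/2] over
    p, q, r in 1..K, keeping only in-bounds neighbors, and divide by the
    number kept.
    """
    c, d, h, w = x.shape
    out = np.zeros_like(x, dtype=np.float64)
    half = (k + 1) // 2
    for i in range(d):
        for j in range(h):
            for l in range(w):
                acc = np.zeros(c)
                cnt = 0
                for p in range(1, k + 1):
                    for q in range(1, k + 1):
                        for r in range(1, k + 1):
                            ii, jj, ll = i + p - half, j + q - half, l + r - half
                            if 0 <= ii < d and 0 <= jj < h and 0 <= ll < w:
                                acc += x[:, ii, jj, ll]
                                cnt += 1
                out[:, i, j, l] = acc / cnt
    return out


class TestAveragePoolMixer:
    @pytest.mark.parametrize("kernel", [3, 5])
    def test_matches_nested_loop_oracle(self, kernel):
        for _ in range(10):
            shape = (int(RNG.integers(1, 3)),) + tuple(RNG.integers(1, 6, 3))
            x = RNG.normal(size=shape)
            got = average_pool_mixer(x, PoolingSpec(kernel))
            np.testing.assert_allclose(got, pooled_by_nested_loops(x, kernel), atol=1e-6)

    def test_worked_slab_center_and_corner(self):
        # single-channel 1x3x3 slab; K=3 center = mean of all 9 = 5,
        # corner = mean{1,2,4,5} = 3 under exclude-padded borders
        slab = np.arange(1.0, 10.0).reshape(1, 1, 3, 3)
        out = average_pool_mixer(slab, PoolingSpec(3))
        assert out[0, 0, 1, 1] == pytest.approx(5.0)
        assert out[0, 0, 0, 0] == pytest.approx(3.0)

    @pytest.mark.parametrize("kernel", [1, 3, 5])
    def test_constant_field_identity(self, kernel):
        x = np.full((2, 4, 5, 3), 2.75)
        out = average_pool_mixer(x, PoolingSpec(kernel))
        np.testing.assert_allclose(out, x, atol=1e-9)

    def test_subtract_identity_gives_zero_on_constant(self):
        x = np.full((1, 4, 4, 4), -1.5)
        out = average_pool_mixer(x, PoolingSpec(3, subtract_identity=True))
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_featuremap_roundtrip_and_errors(self):
        fm = FeatureMap(RNG.normal(size=(2, 3, 3, 3)))
        assert isinstance(average_pool_mixer(fm), FeatureMap)
        with pytest.raises(ValueError):
            PoolingSpec(4)  # even kernel: no centered window
        with pytest.raises(ValueError):
            average_pool_mixer(np.zeros((1, 0, 3, 3)))

    def test_zero_trainable_parameters(self):
        assert PoolingMixer(PoolingSpec(3)).num_parameters() == 0
        assert PoolingMixer(PoolingSpec(5, subtract_identity=True)).num_parameters() == 0


class TestWindowAttention:
    def test_parameter_count_closed_form(self):
        dim, heads, window = 24, 3, 7
        attn = WindowAttention(dim, heads, window)
        expected = (3 * dim * dim + 3 * dim) + (dim * dim + dim) + (2 * window - 1) ** 3 * heads
        assert attn.num_parameters() == expected

    def test_zero_logits_give_uniform_attention(self):
        # q and k projections zero, v = identity, output proj = identity:
        # every output row is the window mean of the inputs
        dim, n = 6, 10
        attn = WindowAttention(dim, heads=2, window=3)
        attn.qkv.weight.data[:] = 0.0
        attn.qkv.bias.data[:] = 0.0
        attn.qkv.weight.data[2 * dim:, :] = np.eye(dim)
        attn.proj.weight.data[:] = np.eye(dim)
        attn.proj.bias.data[:] = 0.0
        attn.relative_position_bias_table.data[:] = 0.0
        tokens = Tensor(RNG.normal(size=(1, n, dim)))
        # a 1x2x5 window holds exactly the n tokens
        out = attn(tokens, window=(1, 2, 5))
        expected = np.broadcast_to(tokens.data.mean(axis=1, keepdims=True), out.shape)
        np.testing.assert_allclose(out.data, expected, atol=1e-6)

    def test_dim_not_divisible_by_heads_raises(self):
        with pytest.raises(ValueError):
            WindowAttention(10, heads=3, window=7)


class TestSqueezeExcitation:
    def test_zero_expansion_weights_halve_input(self):
        x = RNG.normal(size=(4, 3, 3, 3))
        cfg = SEConfig(channels=4, reduction_ratio=4)
        w1 = RNG.normal(size=(1, 4))
        weights = (w1, np.zeros(1), np.zeros((4, 1)), np.zeros(4))
        np.testing.assert_allclose(se_recalibrate(x, cfg, weights), x / 2.0, atol=1e-7)

    def test_hand_computed_two_channel_instance(self):
        # 2-channel 1x1x1 input (4, 0); 2->1->2 bottleneck with chosen weights
        x = np.array([4.0, 0.0]).reshape(2, 1, 1, 1)
        w1, b1 = np.array([[0.5, -1.0]]), np.array([0.0])    # hidden = relu(2) = 2
        w2, b2 = np.array([[1.0], [-1.0]]), np.array([0.0, 1.0])
        # gates = sigmoid([2, -1]) = (0.880797, 0.268941)
        out = se_recalibrate(x, SEConfig(2, 2), (w1, b1, w2, b2))
        expected = x * np.array([0.8807970779778823, 0.2689414213699951]).reshape(2, 1, 1, 1)
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_gates_bounded_and_magnitude_non_expansive(self):
        block = SEBlock(8, reduction=4, rng=np.random.default_rng(3))
        x = Tensor(RNG.normal(size=(2, 8, 3, 3, 3)).astype(np.float64))
        out = block(x)
        assert np.all(np.abs(out.data) <= np.abs(x.data) + 1e-12)
        ratio = out.data / np.where(x.data == 0, 1, x.data)
        assert ratio[x.data != 0].min() > 0.0 and ratio[x.data != 0].max() < 1.0

    def test_channel_mismatch_and_bad_reduction(self):
        with pytest.raises(ValueError):
            se_recalibrate(np.zeros((3, 2, 2, 2)), SEConfig(4, 4),
                           (np.zeros((1, 4)), np.zeros(1), np.zeros((4, 1)), np.zeros(4)))
        with pytest.raises(ValueError):
            SEConfig(channels=6, reduction_ratio=4)


class TestMetaSwinBlock:
    def test_pooling_block_parameter_tally(self):
        d, ratio = 16, 4.0
        blk = MetaSwinBlock(d, mixer="pooling", mlp_ratio=ratio)
        norms = 2 * (2 * d)
        ffn = d * 4 * d + 4 * d + 4 * d * d + d
        assert blk.num_parameters() == norms + ffn  # mixer contributes 0

    @pytest.mark.parametrize("dim,heads", [(6, 3), (12, 3), (24, 6)])
    def test_attention_block_has_strictly_more_parameters(self, dim, heads):
        pool = MetaSwinBlock(dim, mixer="pooling", heads=heads)
        attn = MetaSwinBlock(dim, mixer="attention", heads=heads)
        assert attn.num_parameters() > pool.num_parameters()

    def test_shape_preserved_and_finite(self):
        for mixer, shifted in [("pooling", False), ("attention", False), ("attention", True)]:
            blk = MetaSwinBlock(6, mixer=mixer, heads=3, window=4, shifted=shifted,
                                rng=np.random.default_rng(5))
            x = Tensor(RNG.normal(size=(1, 6, 5, 6, 7)).astype(np.float64))
            out = blk(x)
            assert out.shape == x.shape
            assert np.isfinite(out.data).all()

    def test_residual_identity_on_channelwise_constant_input(self):
        # zeroed feed-forward + identity-subtracting pooling: the block
        # reduces to the residual path exactly
        blk = MetaSwinBlock(4, mixer="pooling",
                            pool_spec=PoolingSpec(3, subtract_identity=True))
        blk.mlp.fc1.weight.data[:] = 0.0
        blk.mlp.fc2.weight.data[:] = 0.0
        x = Tensor(np.broadcast_to(RNG.normal(size=(1, 4, 1, 1, 1)),
                                   (1, 4, 4, 4, 4)).copy())
        np.testing.assert_allclose(blk(x).data, x.data, atol=1e-6)

    def test_channel_mismatch_raises(self):
        blk = MetaSwinBlock(8, mixer="pooling")
        with pytest.raises(ValueError):
            blk(Tensor(np.zeros((1, 4, 4, 4, 4))))


class TestPatchEmbedAndMerge:
    def test_embedding_halves_extents_and_sets_channels(self):
        emb = PatchEmbed(4, 12)
        out = emb(Tensor(RNG.normal(size=(1, 4, 32, 16, 8))))
        assert out.shape == (1, 12, 16, 8, 4)
        with pytest.raises(ValueError):
            emb(Tensor(np.zeros((1, 4, 7, 8, 8))))

    def test_embedding_parameter_delta_between_channel_configs(self):
        four = PatchEmbed(4, 48).num_parameters()
        one = PatchEmbed(1, 48).num_parameters()
        assert four - one == 3 * 48 * 8

    def test_merge_halves_extents_doubles_channels(self):
        merge = PatchMerging(6)
        out = merge(Tensor(RNG.normal(size=(1, 6, 8, 8, 8))))
        assert out.shape == (1, 12, 4, 4, 4)

    def test_three_merges_compose_to_eightfold_channels(self):
        x = Tensor(RNG.normal(size=(1, 4, 16, 16, 16)))
        dims = [4, 8, 16]
        for d in dims:
            x = PatchMerging(d)(x)
        assert x.shape == (1, 32, 2, 2, 2)

    def test_merge_of_constant_field_is_constant(self):
        merge = PatchMerging(5, rng=np.random.default_rng(2))
        x = Tensor(np.broadcast_to(RNG.normal(size=(1, 5, 1, 1, 1)),
                                   (1, 5, 6, 6, 6)).copy())
        out = merge(x).data
        spatial_sd = out.std(axis=(2, 3, 4))
        np.testing.assert_allclose(spatial_sd, 0.0, atol=1e-6)

    def test_merge_pads_odd_extent(self):
        merge = PatchMerging(3)
        out = merge(Tensor(RNG.normal(size=(1, 3, 5, 4, 4))))
        assert out.shape == (1, 6, 3, 2, 2)
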