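"""Patch slicing, token projection and mixer-layer laws.

Slicing/unslicing must be a bijection; mixer sublayers must satisfy their
permutation-equivariance laws (channel mixing commutes with token
permutations, token mixing with channel permutations); token counts obey
n_p = (side/p)^2.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wheatcount as wc
from wheatcount import nn
from wheatcount.mpm import MPM, MixerLayer, MPMConfig, ScaleBranch


@pytest.fixture
def rng():
    return np.random.default_rng(11)


class TestSlicing:
    @pytest.mark.parametrize("p, expected", [(16, 16), (8, 64), (4, 256)])
    def test_patch_counts_on_the_full_geometry(self, p, expected):
        m_f = np.zeros((1, 512, 64, 64), np.float32)
        stack = wc.slice_patches(m_f, p)
        assert stack.shape == (1, expected, 512, p, p)

    def test_full_side_slice_is_identity(self, rng):
        m_f = rng.standard_normal((1, 3, 8, 8)).astype(np.float32)
        stack = wc.slice_patches(m_f, 8)
        assert stack.shape == (1, 1, 3, 8, 8)
        assert np.array_equal(stack.data[0, 0], m_f[0])

    def test_row_major_tile_order(self, rng):
        # encode the tile index in the map and read it back
        m_f = np.arange(16, dtype=np.float32).reshape(4, 4)[None, None]
        m_f = np.repeat(m_f, 2, axis=1)
        stack = wc.slice_patches(m_f, 2).data
        top_left = stack[0, :, 0, 0, 0]
        assert np.array_equal(top_left, [0, 2, 8, 10])

    def test_indivisible_slice_rejected(self):
        with pytest.raises(ValueError, match="5"):
            wc.slice_patches(np.zeros((1, 2, 8, 8), np.float32), 5)

    @given(st.sampled_from([(8, 2), (8, 4), (12, 3), (6, 6)]),
           st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_slice_unslice_bijection(self, geometry, seed):
        side, p = geometry
        x = np.random.default_rng(seed).standard_normal(
            (2, 3, side, side)).astype(np.float32)
        stack = wc.slice_patches(x, p)
        back = wc.unslice_patches(stack, p, side)
        assert np.array_equal(back.data, x)

    def test_shuffled_stack_differs_unless_identity(self, rng):
        x = rng.standard_normal((1, 2, 8, 8)).astype(np.float32)
        stack = wc.slice_patches(x, 4).data
        perm = np.array([1, 0, 2, 3])
        shuffled = wc.unslice_patches(stack[:, perm], 4, 8).data
        assert not np.array_equal(shuffled, x)

    def test_inconsistent_geometry_rejected(self):
        with pytest.raises(ValueError):
            wc.unslice_patches(np.zeros((1, 3, 2, 4, 4), np.float32), 4, 12)


class TestProjection:
    def test_zero_stack_zero_bias_gives_zero_tokens(self, rng):
        proj = nn.Linear(2 * 4 * 4, 6, rng)
        stack = nn.Tensor(np.zeros((1, 4, 2, 4, 4)))
        assert np.allclose(wc.project_tokens(stack, proj).data, 0.0)

    def test_identity_projection_returns_flattened_patches(self, rng):
        d = 2 * 3 * 3
        proj = nn.Linear(d, d, rng)
        proj.weight.data = np.eye(d, dtype=np.float32)
        proj.bias.data[:] = 0
        stack = rng.standard_normal((1, 4, 2, 3, 3)).astype(np.float32)
        out = wc.project_tokens(nn.Tensor(stack), proj).data
        assert np.allclose(out, stack.reshape(1, 4, d), atol=1e-6)

    def test_matches_matrix_product_oracle(self, rng):
        proj = nn.Linear(8, 5, rng)
        stack = rng.standard_normal((2, 3, 2, 2, 2)).astype(np.float32)
        out = wc.project_tokens(nn.Tensor(stack), proj).data
        flat = stack.reshape(2, 3, 8)
        expected = flat @ proj.weight.data + proj.bias.data
        assert np.allclose(out, expected, atol=1e-5)


class TestMixerLayer:
    def test_zero_input_zero_biases_gives_zero(self, rng):
        layer = MixerLayer(6, 8, 4, 16, rng)
        out = layer(nn.Tensor(np.zeros((1, 6, 8))))
        assert np.allclose(out.data, 0.0, atol=1e-6)

    def test_channel_sublayer_token_permutation_equivariance(self, rng):
        layer = MixerLayer(6, 8, 4, 16, rng)
        t = nn.Tensor(rng.standard_normal((1, 6, 8)).astype(np.float32))
        perm = rng.permutation(6)
        direct = layer.channel_sublayer(t).data[:, perm]
        permuted = layer.channel_sublayer(nn.Tensor(t.data[:, perm])).data
        assert np.allclose(direct, permuted, atol=1e-5)

    def test_token_sublayer_channel_permutation_equivariance(self, rng):
        layer = MixerLayer(6, 8, 4, 16, rng)
        # LayerNorm scale/shift must be channel-symmetric for this law
        layer.norm1.gamma.data[:] = 1.3
        layer.norm1.beta.data[:] = -0.2
        t = nn.Tensor(rng.standard_normal((1, 6, 8)).astype(np.float32))
        perm = rng.permutation(8)
        direct = layer.token_sublayer(t).data[..., perm]
        permuted = layer.token_sublayer(nn.Tensor(t.data[..., perm])).data
        assert np.allclose(direct, permuted, atol=1e-5)

    def test_scale_branch_composes_mixers(self, rng):
        cfg = MPMConfig(slices=(4,), embed_dim=8, depth=3,
                        token_hidden=4, channel_hidden=16)
        branch = ScaleBranch(4, 8, 2, cfg, rng)
        m_f = nn.Tensor(rng.standard_normal((1, 2, 8, 8)).astype(np.float32))
        out = branch(m_f).data
        t = wc.project_tokens(wc.slice_patches(m_f, 4), branch.projection)
        for layer in branch.mixers:
            t = layer(t)
        assert np.allclose(out, t.data, atol=1e-6)

    def test_depth_zero_branch_is_projection_only(self, rng):
        cfg = MPMConfig(slices=(4,), embed_dim=8, depth=0,
                        token_hidden=4, channel_hidden=16)
        branch = ScaleBranch(4, 8, 2, cfg, rng)
        m_f = nn.Tensor(rng.standard_normal((1, 2, 8, 8)).astype(np.float32))
        expected = wc.project_tokens(wc.slice_patches(m_f, 4), branch.projection)
        assert np.allclose(branch(m_f).data, expected.data, atol=1e-7)


class TestMergeAndMix:
    def test_merged_token_count_is_branch_sum(self, rng):
        cfg = MPMConfig(slices=(8, 4, 2), embed_dim=8, depth=1,
                        token_hidden=4, channel_hidden=16)
        mpm = MPM(side=8, in_channels=2, config=cfg, rng=rng)
        m_f = nn.Tensor(rng.standard_normal((1, 2, 8, 8)).astype(np.float32))
        out = mpm(m_f)
        assert out.shape == (1, 1 + 4 + 16, 8)
        assert mpm.total_tokens == 21

    def test_full_geometry_merges_336_tokens(self):
        cfg = MPMConfig(slices=(16, 8, 4), embed_dim=8, depth=0,
                        token_hidden=4, channel_hidden=8, merge=False)
        mpm = MPM(side=64, in_channels=1, config=cfg,
                  rng=np.random.default_rng(0))
        assert mpm.total_tokens == 16 + 64 + 256 == 336

    def test_merge_without_mixing_is_concatenation(self, rng):
        cfg = MPMConfig(slices=(8, 4), embed_dim=8, depth=0,
                        token_hidden=4, channel_hidden=16)
        mpm = MPM(side=8, in_channels=2, config=cfg, rng=rng)
        m_f = nn.Tensor(rng.standard_normal((1, 2, 8, 8)).astype(np.float32))
        out = mpm(m_f).data
        parts = [b(m_f).data for b in mpm.branches]
        assert np.allclose(out, np.concatenate(parts, axis=1), atol=1e-7)

    def test_branch_order_is_coarse_to_fine(self, rng):
        cfg = MPMConfig(slices=(4, 8), embed_dim=8, depth=0,
                        token_hidden=4, channel_hidden=16)
        mpm = MPM(side=8, in_channels=2, config=cfg, rng=rng)
        assert [b.p for b in mpm.branches] == [8, 4]

    def test_mismatched_embed_dims_rejected(self, rng):
        from wheatcount.mpm import merge_and_mix
        with pytest.raises(ValueError):
            merge_and_mix([nn.Tensor(np.zeros((1, 4, 8))),
                           nn.Tensor(np.zeros((1, 4, 6)))], [])

    def test_indivisible_slice_size_rejected_at_build(self, rng):
        cfg = MPMConfig(slices=(5,), embed_dim=8, depth=0,
                        token_hidden=4, channel_hidden=16)
        with pytest.raises(ValueError):
            MPM(side=8, in_channels=2, config=cfg, rng=rng)
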