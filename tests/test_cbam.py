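"""Channel and spatial attention against explicit-loop oracles.

The oracle recomputes the attention chain with plain Python loops and numpy
scalars, independent of the layer implementations.
"""

import numpy as np
import pytest

import wheatcount as wc
from wheatcount import nn
from wheatcount.cbam import CBAM, ChannelAttention, SpatialAttention, apply_channel


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def oracle_channel_attention(m_b, w1, b1, w2, b2):
    """sigmoid(FC(maxpool) + FC(avgpool)), shared bottleneck, per sample."""
    out = np.zeros(m_b.shape[:2])
    for n in range(m_b.shape[0]):
        mx = np.array([m_b[n, c].max() for c in range(m_b.shape[1])])
        av = np.array([m_b[n, c].mean() for c in range(m_b.shape[1])])
        fc = lambda v: np.maximum(v @ w1 + b1, 0) @ w2 + b2
        out[n] = sigmoid(fc(mx) + fc(av))
    return out


def oracle_spatial_attention(m_cb, kernel, bias, k):
    """sigmoid(conv(concat(max_c, avg_c))) with an explicit loop conv."""
    n_, c_, h, w = m_cb.shape
    out = np.zeros((n_, h, w))
    pad = k // 2
    for n in range(n_):
        planes = np.stack([m_cb[n].max(axis=0), m_cb[n].mean(axis=0)])
        padded = np.pad(planes, ((0, 0), (pad, pad), (pad, pad)))
        for i in range(h):
            for j in range(w):
                acc = bias
                for c in range(2):
                    for a in range(k):
                        for b in range(k):
                            acc += kernel[c, a, b] * padded[c, i + a, j + b]
                out[n, i, j] = sigmoid(acc)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(77)


class TestChannelAttention:
    def test_zero_input_zero_bias_gives_half(self, rng):
        ca = ChannelAttention(8, reduction=2, rng=rng)
        ca.fc1.bias.data[:] = 0
        ca.fc2.bias.data[:] = 0
        out = ca(nn.Tensor(np.zeros((1, 8, 4, 4))))
        assert np.allclose(out.data, 0.5)  # sigmoid(0)

    def test_matches_explicit_loop_oracle(self, rng):
        ca = ChannelAttention(4, reduction=2, rng=rng)
        m_b = rng.standard_normal((3, 4, 5, 5)).astype(np.float32)
        out = ca(nn.Tensor(m_b)).data
        expected = oracle_channel_attention(
            m_b, ca.fc1.weight.data, ca.fc1.bias.data,
            ca.fc2.weight.data, ca.fc2.bias.data)
        assert np.allclose(out, expected, atol=1e-5)

    def test_too_large_reduction_rejected(self, rng):
        with pytest.raises(ValueError):
            ChannelAttention(4, reduction=16, rng=rng)


class TestApplyChannel:
    def test_unit_weights_identity(self, rng):
        m_b = nn.Tensor(rng.standard_normal((2, 3, 4, 4)))
        ones = nn.Tensor(np.ones((2, 3)))
        assert np.allclose(apply_channel(ones, m_b).data, m_b.data)

    def test_uniform_half_halves(self, rng):
        m_b = nn.Tensor(rng.standard_normal((1, 5, 3, 3)))
        half = nn.Tensor(np.full((1, 5), 0.5))
        assert np.allclose(apply_channel(half, m_b).data, m_b.data / 2)

    def test_random_broadcast_product(self, rng):
        m_b = rng.standard_normal((2, 4, 3, 3)).astype(np.float32)
        m_c = rng.random((2, 4)).astype(np.float32)
        out = apply_channel(nn.Tensor(m_c), nn.Tensor(m_b)).data
        assert np.allclose(out, m_c[:, :, None, None] * m_b, atol=1e-7)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_channel(nn.Tensor(np.ones((1, 3))),
                          nn.Tensor(np.ones((1, 4, 2, 2))))


class TestSpatialAttention:
    def test_zero_input_zero_bias_gives_half(self, rng):
        sa = SpatialAttention(kernel=7, rng=rng)
        out = sa(nn.Tensor(np.zeros((1, 6, 8, 8))))
        assert np.allclose(out.data, 0.5)

    def test_delta_kernel_selects_channel_max(self, rng):
        sa = SpatialAttention(kernel=3, rng=rng)
        sa.conv.weight.data[:] = 0
        sa.conv.weight.data[0, 0, 1, 1] = 1.0  # centre tap on the max plane
        sa.conv.bias.data[:] = 0
        m_cb = rng.standard_normal((2, 5, 6, 6)).astype(np.float32)
        out = sa(nn.Tensor(m_cb)).data[:, 0]
        expected = 1 / (1 + np.exp(-m_cb.max(axis=1)))
        assert np.allclose(out, expected, atol=1e-6)

    def test_matches_explicit_loop_oracle(self, rng):
        sa = SpatialAttention(kernel=3, rng=rng)
        m_cb = rng.standard_normal((2, 4, 5, 5)).astype(np.float32)
        out = sa(nn.Tensor(m_cb)).data[:, 0]
        expected = oracle_spatial_attention(
            m_cb, sa.conv.weight.data[0], float(sa.conv.bias.data[0]), 3)
        assert np.allclose(out, expected, atol=1e-5)


class TestCBAMForward:
    def test_zero_in_zero_out(self, rng):
        cbam = CBAM(8, rng, reduction=2)
        out = cbam(nn.Tensor(np.zeros((1, 8, 4, 4))))
        assert np.allclose(out.data, 0.0)

    def test_attenuation_bound(self, rng):
        cbam = CBAM(8, rng, reduction=2)
        m_b = rng.standard_normal((3, 8, 6, 6)).astype(np.float32)
        m_f = cbam(nn.Tensor(m_b)).data
        assert m_f.shape == m_b.shape
        assert np.all(np.abs(m_f) <= np.abs(m_b) + 1e-7)

    def test_full_chain_matches_oracle(self, rng):
        cbam = CBAM(8, rng, reduction=2, spatial_kernel=3)
        m_b = rng.standard_normal((2, 8, 6, 6)).astype(np.float32)
        m_f = cbam(nn.Tensor(m_b)).data
        m_c = oracle_channel_attention(
            m_b, cbam.channel.fc1.weight.data, cbam.channel.fc1.bias.data,
            cbam.channel.fc2.weight.data, cbam.channel.fc2.bias.data)
        m_cb = m_c[:, :, None, None] * m_b
        m_s = oracle_spatial_attention(
            m_cb, cbam.spatial.conv.weight.data[0],
            float(cbam.spatial.conv.bias.data[0]), 3)
        assert np.allclose(m_f, m_s[:, None] * m_cb, atol=1e-5)

    def test_passthrough_mode_is_identity(self, rng):
        cbam = CBAM(8, rng, reduction=2, enabled=False)
        m_b = nn.Tensor(rng.standard_normal((1, 8, 4, 4)))
        assert cbam(m_b) is m_b
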