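"""Convolutional block attention: channel attention then spatial attention.

Given a backbone feature map M_b, channel attention computes per-channel
weights

    M_c = sigmoid(FC(maxpool_spatial(M_b)) + FC(avgpool_spatial(M_b)))

with one shared two-layer bottleneck (reduction ratio r, ReLU between the
layers) applied to both pooled descriptors, and rescales channels,
M_cb = M_c * M_b.  Spatial attention then pools over channels, convolves the
two pooled planes with a single k x k kernel and squashes,

    M_s = sigmoid(conv(concat(maxpool_channel(M_cb), avgpool_channel(M_cb))))

and the refined map is M_f = M_s * M_cb.  Both attention stages multiply by
sigmoid outputs, so |M_f| <= |M_b| elementwise.  A pass-through mode
(``enabled=False``) returns M_b untouched for ablations.
"""

from __future__ import annotations

import numpy as np

from . import nn


class ChannelAttention(nn.Module):
    """Shared-bottleneck channel attention over spatially pooled descriptors."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = channels // reduction
        if hidden < 1:
            raise ValueError(
                f"reduction {reduction} too large for {channels} channels")
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, channels, rng)

    def _bottleneck(self, v: nn.Tensor) -> nn.Tensor:
        return self.fc2(nn.relu(self.fc1(v)))

    def forward(self, m_b: nn.Tensor) -> nn.Tensor:
        mx = self._bottleneck(nn.global_max_pool(m_b))
        av = self._bottleneck(nn.global_avg_pool(m_b))
        return nn.sigmoid(mx + av)  # (N, C)


class SpatialAttention(nn.Module):
    """Single-conv spatial attention over channel-pooled planes."""

    def __init__(self, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, kernel, rng)

    def forward(self, m_cb: nn.Tensor) -> nn.Tensor:
        pooled = nn.concat([nn.channel_max_pool(m_cb),
                            nn.channel_avg_pool(m_cb)], axis=1)
        return nn.sigmoid(self.conv(pooled))  # (N, 1, H, W)


def apply_channel(m_c: nn.Tensor, m_b: nn.Tensor) -> nn.Tensor:
    """Broadcast the per-channel weights (N, C) over the map (N, C, H, W)."""
    if m_c.shape[1] != m_b.shape[1]:
        raise ValueError(f"channel mismatch: {m_c.shape[1]} != {m_b.shape[1]}")
    return m_c.reshape(m_c.shape[0], m_c.shape[1], 1, 1) * m_b


class CBAM(nn.Module):
    """Channel-then-spatial attention refinement of a feature map."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 16, spatial_kernel: int = 7,
                 enabled: bool = True):
        super().__init__()
        self.enabled = enabled
        if enabled:
            self.channel = ChannelAttention(channels, reduction, rng)
            self.spatial = SpatialAttention(spatial_kernel, rng)

    def forward(self, m_b: nn.Tensor) -> nn.Tensor:
        if not self.enabled:
            return m_b
        m_cb = apply_channel(self.channel(m_b), m_b)
        m_s = self.spatial(m_cb)
        return m_s * m_cb
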