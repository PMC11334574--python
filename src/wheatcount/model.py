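"""Assembly of the full count-regression network.

Backbone -> (optional) channel+spatial attention -> multiscale mixer
perception -> counting head.  :class:`CountingNetwork` validates that the
configured pieces are geometrically consistent at build time (slice sizes
must divide the feature side; the head's input dim is derived from the token
geometry) and exposes named intermediate activations for gradient-based
visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import Backbone, BackboneConfig
from .cbam import CBAM
from .head import CountingHead, CountPrediction, HeadConfig
from .mpm import MPM, MPMConfig


@dataclass
class ModelConfig:
    """Full network configuration plus the input image side it expects."""

    image_size: int = 512
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    cbam: bool = True
    cbam_reduction: int = 16
    mpm: MPMConfig = field(default_factory=MPMConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    seed: int = 0

    @classmethod
    def tiny(cls, seed: int = 0) -> "ModelConfig":
        """Desk-scale variant: 1/16-width backbone, 128 px input, slices 8/4."""
        return cls(
            image_size=128,
            backbone=BackboneConfig(width_multiplier=1 / 16),
            cbam=True,
            cbam_reduction=4,
            mpm=MPMConfig(slices=(8, 4), embed_dim=64, depth=2,
                          token_hidden=32, channel_hidden=128),
            head=HeadConfig(hidden=256, dropout=0.5, k=16),
            seed=seed,
        )


class CountingNetwork(nn.Module):
    """Image batch (N, 3, S, S) -> nonnegative count per image."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        self.config = config
        s = config.image_size
        stride = config.backbone.stride
        if s % stride:
            raise ValueError(f"image size {s} not divisible by backbone stride {stride}")
        side = s // stride
        for p in config.mpm.slices:
            if side % p:
                raise ValueError(
                    f"slice size {p} does not divide feature side {side} "
                    f"(image {s} / stride {stride})")
        self.backbone = Backbone(config.backbone, rng)
        channels = config.backbone.out_channels
        self.cbam = CBAM(channels, rng, reduction=config.cbam_reduction,
                         enabled=config.cbam)
        self.mpm = MPM(side, channels, config.mpm, rng)
        head_in = self.mpm.total_tokens * config.mpm.embed_dim
        self.head = CountingHead(head_in, config.head, rng)
        self.feature_side = side
        # intermediate activations by tag, refreshed each forward
        self.taps: dict[str, nn.Tensor] = {}

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        m_b = self.backbone(x)
        m_f = self.cbam(m_b)
        t_all = self.mpm(m_f)
        c_hat, x2 = self.head(t_all)
        self.taps = {"backbone": m_b}
        for p, t in self.mpm.branch_outputs.items():
            self.taps[f"mpm{p}"] = t
        return c_hat, x2

    def predict(self, images: np.ndarray) -> CountPrediction:
        """Eval-mode forward without building the autodiff tape."""
        self.eval()
        with nn.no_grad():
            c_hat, x2 = self.forward(nn.Tensor(images))
        return CountPrediction(count=c_hat.data.copy(), count_set=x2.data.copy())


def assemble_model(config: ModelConfig | None = None) -> CountingNetwork:
    """Build the full count regressor; raises on inconsistent configuration."""
    return CountingNetwork(config or ModelConfig())
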