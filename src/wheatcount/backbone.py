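"""Truncated VGG-style backbone: 10 3x3 convolutions, 3 max-pools, stride 8.

The feature extractor keeps the first four convolutional blocks of the
classical VGG16 layout (64,64 | 128,128 | 256,256,256 | 512,512,512, ReLU
after every convolution, no batch norm) with a 2x2 stride-2 max-pool after
each of the first three blocks, so a 3 x H x W image maps to a
512 x H/8 x W/8 feature map.  A width multiplier scales every channel count
for desk-scale variants that train in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

VGG_BLOCKS: tuple[tuple[int, ...], ...] = ((64, 64), (128, 128), (256, 256, 256),
                                           (512, 512, 512))


@dataclass
class BackboneConfig:
    """Configuration of the truncated VGG feature extractor.

    ``blocks`` lists convolution widths per block; a max-pool follows each
    block except the last, giving output stride ``2**(len(blocks)-1)``.
    ``width_multiplier`` in (0, 1] scales every width (minimum 1 channel).
    """

    blocks: tuple[tuple[int, ...], ...] = VGG_BLOCKS
    width_multiplier: float = 1.0
    pretrained_weights: str | None = None  # optional .npz path, loaded if given

    def __post_init__(self):
        if not 0.0 < self.width_multiplier <= 1.0:
            raise ValueError("width_multiplier must be in (0, 1]")
        if any(w <= 0 for blk in self.blocks for w in blk):
            raise ValueError("channel widths must be positive")

    @property
    def widths(self) -> list[list[int]]:
        return [[max(1, int(round(w * self.width_multiplier))) for w in blk]
                for blk in self.blocks]

    @property
    def stride(self) -> int:
        return 2 ** (len(self.blocks) - 1)

    @property
    def out_channels(self) -> int:
        return self.widths[-1][-1]


class Backbone(nn.Module):
    """Sequential conv/ReLU blocks with inter-block max pooling."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.convs: list[nn.Conv2d] = []
        self.pool_after: set[int] = set()
        in_ch = 3
        idx = 0
        widths = config.widths
        for b, blk in enumerate(widths):
            for w in blk:
                self.convs.append(nn.Conv2d(in_ch, w, 3, rng))
                in_ch = w
                idx += 1
            if b < len(widths) - 1:
                self.pool_after.add(idx - 1)
        self.pool = nn.MaxPool2x2()
        if config.pretrained_weights:
            state = np.load(config.pretrained_weights)
            self.load_state_dict({k: state[k] for k in state.files})

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        n, c, h, w = x.shape
        s = self.config.stride
        if h % s or w % s:
            raise ValueError(f"input sides must be divisible by {s}, got {h}x{w}")
        for i, conv in enumerate(self.convs):
            x = nn.relu(conv(x))
            if i in self.pool_after:
                x = self.pool(x)
        return x


def build_backbone(config: BackboneConfig | None = None,
                   rng: np.random.Generator | None = None) -> Backbone:
    """Build the feature extractor; seeded init via ``rng``."""
    config = config or BackboneConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    return Backbone(config, rng)


def extract_features(backbone: Backbone, images: np.ndarray) -> np.ndarray:
    """Run preprocessed images (N, 3, H, W) through the backbone, no gradients."""
    with nn.no_grad():
        return backbone(nn.Tensor(images)).data
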