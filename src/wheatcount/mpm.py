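"""Multiscale perception: patch slicing, token projection and mixer stacks.

The refined feature map M_f (C x S x S) is sliced into non-overlapping p x p
tiles at several slice sizes (default 16, 8 and 4 on a 64 x 64 map, giving
16, 64 and 256 patches).  Each branch flattens its tiles, projects them with
an independent linear map to a shared embedding dimension d, and applies N
mixer layers.  A mixer layer is two pre-norm residual sublayers: token mixing
(transpose so the MLP runs across the patch axis) and channel mixing (MLP
across the embedding axis).  The branch token matrices T_1..T_3 are
concatenated along the token axis, coarse to fine, and mixed again by a
merge stack of N mixer layers to give T_all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn


@dataclass
class MPMConfig:
    """Slice sizes, shared embedding dim and mixer dimensions.

    ``depth`` is the number of mixer layers per scale branch and, when
    ``merge`` is true, also of the merging stack.
    """

    slices: tuple[int, ...] = (16, 8, 4)
    embed_dim: int = 512
    depth: int = 4
    token_hidden: int = 256
    channel_hidden: int = 1024
    merge: bool = True

    def __post_init__(self):
        if len(set(self.slices)) != len(self.slices) or not self.slices:
            raise ValueError("slices must be non-empty and distinct")
        if min(self.slices) < 1 or self.embed_dim < 1 or self.depth < 0:
            raise ValueError("invalid MPM dimensions")


def slice_patches(feature_map: np.ndarray | nn.Tensor, p: int) -> nn.Tensor:
    """Tile (N, C, H, W) into (N, n_p, C, p, p), row-major, n_p = (H/p)(W/p)."""
    x = feature_map if isinstance(feature_map, nn.Tensor) else nn.Tensor(feature_map)
    n, c, h, w = x.shape
    if h % p or w % p:
        raise ValueError(f"slice size {p} does not divide map side {h}x{w}")
    gh, gw = h // p, w // p
    return (x.reshape(n, c, gh, p, gw, p)
             .transpose(0, 2, 4, 1, 3, 5)
             .reshape(n, gh * gw, c, p, p))


def unslice_patches(stack: np.ndarray | nn.Tensor, p: int, side: int) -> nn.Tensor:
    """Inverse of :func:`slice_patches`; exact round trip."""
    x = stack if isinstance(stack, nn.Tensor) else nn.Tensor(stack)
    n, n_p, c = x.shape[0], x.shape[1], x.shape[2]
    g = side // p
    if g * g != n_p or g * p != side:
        raise ValueError(f"stack of {n_p} patches at size {p} "
                         f"is inconsistent with side {side}")
    return (x.reshape(n, g, g, c, p, p)
             .transpose(0, 3, 1, 4, 2, 5)
             .reshape(n, c, side, side))


def project_tokens(stack: nn.Tensor, projection: nn.Linear) -> nn.Tensor:
    """Flatten each patch and apply the branch's linear projection -> (N, n_p, d)."""
    n, n_p = stack.shape[0], stack.shape[1]
    flat = stack.reshape(n, n_p, int(np.prod(stack.shape[2:])))
    return projection(flat)


class MLP(nn.Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.fc2(nn.relu(self.fc1(x)))


class MixerLayer(nn.Module):
    """Pre-norm token-mixing then channel-mixing sublayers with residuals."""

    def __init__(self, tokens: int, dim: int, token_hidden: int,
                 channel_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.token_mlp = MLP(tokens, token_hidden, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.channel_mlp = MLP(dim, channel_hidden, rng)

    def token_sublayer(self, t: nn.Tensor) -> nn.Tensor:
        y = self.norm1(t).swapaxes(-1, -2)   # (N, d, tokens)
        y = self.token_mlp(y).swapaxes(-1, -2)
        return t + y

    def channel_sublayer(self, t: nn.Tensor) -> nn.Tensor:
        return t + self.channel_mlp(self.norm2(t))

    def forward(self, t: nn.Tensor) -> nn.Tensor:
        return self.channel_sublayer(self.token_sublayer(t))


class ScaleBranch(nn.Module):
    """One slicing scale: slice -> project -> N mixer layers."""

    def __init__(self, p: int, side: int, in_channels: int, config: MPMConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.side = side
        self.tokens = (side // p) ** 2
        self.projection = nn.Linear(in_channels * p * p, config.embed_dim, rng)
        self.mixers = [MixerLayer(self.tokens, config.embed_dim,
                                  config.token_hidden, config.channel_hidden, rng)
                       for _ in range(config.depth)]

    def forward(self, m_f: nn.Tensor) -> nn.Tensor:
        t = project_tokens(slice_patches(m_f, self.p), self.projection)
        for layer in self.mixers:
            t = layer(t)
        return t


class MPM(nn.Module):
    """Parallel scale branches merged by concatenation and a final mixer stack."""

    def __init__(self, side: int, in_channels: int, config: MPMConfig,
                 rng: np.random.Generator):
        super().__init__()
        for p in config.slices:
            if side % p:
                raise ValueError(f"slice size {p} does not divide feature side {side}")
        self.config = config
        self.branches = [ScaleBranch(p, side, in_channels, config, rng)
                         for p in sorted(config.slices, reverse=True)]  # coarse->fine
        total = sum(b.tokens for b in self.branches)
        self.total_tokens = total
        self.merge_mixers = ([MixerLayer(total, config.embed_dim,
                                         config.token_hidden, config.channel_hidden,
                                         rng)
                              for _ in range(config.depth)]
                             if config.merge else [])
        self.branch_outputs: dict[int, nn.Tensor] = {}  # tap for visualisation

    def forward(self, m_f: nn.Tensor) -> nn.Tensor:
        outs = [b(m_f) for b in self.branches]
        self.branch_outputs = {b.p: t for b, t in zip(self.branches, outs)}
        t_all = merge_and_mix(outs, self.merge_mixers)
        return t_all


def merge_and_mix(branch_tokens: list[nn.Tensor],
                  merge_layers: list[MixerLayer]) -> nn.Tensor:
    """Concatenate branch token matrices along the token axis and mix again."""
    dims = {t.shape[-1] for t in branch_tokens}
    if len(dims) != 1:
        raise ValueError(f"branch embedding dims differ: {sorted(dims)}")
    t_all = (branch_tokens[0] if len(branch_tokens) == 1
             else nn.concat(branch_tokens, axis=1))
    for layer in merge_layers:
        t_all = layer(t_all)
    return t_all
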