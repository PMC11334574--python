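"""Gradient-weighted attention maps for the count regressor.

Classic Grad-CAM targets a class logit; here the scalar of interest is the
predicted count itself.  For a tagged feature layer with activations A_k the
channel weights are the spatial averages of dC_hat/dA_k and the map is

    cam = ReLU(sum_k w_k A_k),

bilinearly upsampled to the input size and min-max normalised to [0, 1]
(an all-zero map stays all-zero).  Mixer-branch token matrices are reshaped
to their (side/p) x (side/p) grid first, so each slicing scale can be
inspected separately; coarser slices produce broader attention footprints.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from . import nn
from .model import CountingNetwork

__all__ = ["compute_cam", "overlay", "layer_tags"]


def layer_tags(model: CountingNetwork) -> list[str]:
    """Valid ``layer`` arguments: the backbone plus one tag per mixer scale."""
    return ["backbone"] + [f"mpm{b.p}" for b in model.mpm.branches]


def _to_spatial(tag: str, activation: np.ndarray, grad: np.ndarray,
                model: CountingNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Return (A, dA) as (C, h, w) arrays for either kind of tap."""
    if tag == "backbone":
        return activation[0], grad[0]
    p = int(tag[3:])
    g = model.feature_side // p
    a = activation[0].reshape(g, g, -1).transpose(2, 0, 1)   # (d, g, g)
    d = grad[0].reshape(g, g, -1).transpose(2, 0, 1)
    return a, d


def compute_cam(model: CountingNetwork, image: np.ndarray, tag: str) -> np.ndarray:
    """Attention heatmap in [0, 1] at input resolution for one image (3, S, S)."""
    model.eval()
    x = nn.Tensor(image[None] if image.ndim == 3 else image)
    c_hat, _ = model(x)
    if tag not in model.taps:
        raise KeyError(f"unknown layer tag {tag!r}; valid: {layer_tags(model)}")
    tap = model.taps[tag].retain_grad()
    c_hat.sum().backward()
    if tap.grad is None:
        raise RuntimeError(f"no gradient reached layer {tag!r} "
                           "(count prediction is saturated at zero)")
    a, g = _to_spatial(tag, tap.data, tap.grad, model)
    weights = g.mean(axis=(1, 2))                            # (C,)
    cam = np.maximum((weights[:, None, None] * a).sum(axis=0), 0.0)
    size = model.config.image_size
    cam = resize(cam, (size, size), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    peak = cam.max()
    return cam / peak if peak > 0 else np.zeros_like(cam)


def overlay(image: np.ndarray, heatmap: np.ndarray, alpha: float = 0.5,
            cmap: str = "jet") -> np.ndarray:
    """Alpha-blend a colormapped heatmap over an (H, W, 3) uint8 image."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if image.shape[:2] != heatmap.shape:
        raise ValueError(f"image {image.shape[:2]} and heatmap {heatmap.shape} "
                         "sizes differ")
    from matplotlib import colormaps
    colors = colormaps[cmap](heatmap)[..., :3] * 255.0
    blend = (1.0 - alpha) * image.astype(np.float64) + alpha * colors
    return np.clip(np.rint(blend), 0, 255).astype(np.uint8)
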