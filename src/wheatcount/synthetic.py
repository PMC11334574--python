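"""Seeded generator of field-like images with exact per-image count labels.

Two modes emulate the statistical structure of wheat-counting benchmarks:

* ``ear_field`` — elongated, textured, randomly oriented ellipses ("ears")
  on a cluttered green-brown canopy.  Default counts follow a clipped
  Gaussian with mean 42, sd 20, clipped to [0, 190], matching the per-image
  marginals of large public wheat-head collections.
* ``grain_scatter`` — small rounded kernels scattered on a plain or
  gray-striped background, emulating tabletop grain photographs; default
  counts are Gaussian mean 40, sd 10, clipped to [11, 68], with explicit
  zero-count background images available as negative samples.

Counts are exact by construction: the label equals the number of instances
actually rendered, and generation is a pure function of (config, seed).
Instance positions are written to a debug sidecar only; the counting network
never sees them, preserving the count-only supervision premise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "SynthConfig",
    "ImageSample",
    "CapacityError",
    "sample_count",
    "render_field",
    "generate_dataset",
    "split_manifest",
]


class CapacityError(RuntimeError):
    """Requested count cannot be packed into the configured image."""


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults emulate the ear-field statistics."""

    mode: str = "ear_field"               # "ear_field" | "grain_scatter"
    image_size: int = 512
    count_mean: float = 42.0
    count_sd: float = 20.0
    count_min: int = 0
    count_max: int = 190
    length_px: tuple[float, float] = (24.0, 44.0)   # object major axis range
    width_px: tuple[float, float] = (8.0, 14.0)     # object minor axis range
    color_jitter: float = 0.15            # relative RGB jitter per object
    clutter_density: float = 0.002        # background streaks per pixel
    stripe_period: int = 48               # grain-mode stripe period, px
    striped_background: bool = False      # grain mode only
    occlusion: float = 0.3                # max fraction of a new object overlapping
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("ear_field", "grain_scatter"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.count_min > self.count_max:
            raise ValueError("count_min must be <= count_max")
        if not 0.0 <= self.occlusion <= 1.0:
            raise ValueError("occlusion must be in [0, 1]")

    @classmethod
    def ear_field(cls, image_size: int = 512, **kw) -> "SynthConfig":
        scale = image_size / 512.0
        return cls(mode="ear_field", image_size=image_size,
                   length_px=(24.0 * scale, 44.0 * scale),
                   width_px=(8.0 * scale, 14.0 * scale), **kw)

    @classmethod
    def grain_scatter(cls, image_size: int = 256, striped: bool = False,
                      **kw) -> "SynthConfig":
        scale = image_size / 256.0
        return cls(mode="grain_scatter", image_size=image_size,
                   count_mean=40.0, count_sd=10.0, count_min=11, count_max=68,
                   length_px=(12.0 * scale, 18.0 * scale),
                   width_px=(6.0 * scale, 9.0 * scale),
                   striped_background=striped, **kw)

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class ImageSample:
    """One rendered image, its exact count, and debug instance positions."""

    image: np.ndarray                      # (H, W, 3) uint8
    count: int
    positions: list[tuple[float, float, float, float, float]] = field(
        default_factory=list)              # (x, y, angle, length, width)


def sample_count(config: SynthConfig, rng: np.random.Generator) -> int:
    """Draw one integer count from the clipped, rounded Gaussian."""
    x = rng.normal(config.count_mean, config.count_sd)
    return int(np.clip(np.rint(x), config.count_min, config.count_max))


def _ellipse_mask(h: int, w: int, cx: float, cy: float, a: float, b: float,
                  angle: float) -> tuple[np.ndarray, tuple[int, int]]:
    """Boolean mask of an oriented ellipse within its clipped bounding box."""
    r = max(a, b)
    x0, x1 = max(0, int(cx - r - 1)), min(w, int(cx + r + 2))
    y0, y1 = max(0, int(cy - r - 1)), min(h, int(cy + r + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    c, s = np.cos(angle), np.sin(angle)
    u = (dx * c + dy * s) / a
    v = (-dx * s + dy * c) / b
    return (u * u + v * v) <= 1.0, (y0, x0)


def _background(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    s = config.image_size
    if config.mode == "ear_field":
        base = np.array([72.0, 96.0, 48.0])          # canopy green-brown
        img = base + rng.normal(0, 10, size=(s, s, 3))
        n_clutter = rng.poisson(config.clutter_density * s * s)
        for _ in range(n_clutter):
            cx, cy = rng.uniform(0, s, 2)
            ang = rng.uniform(0, np.pi)
            mask, (y0, x0) = _ellipse_mask(s, s, cx, cy,
                                           rng.uniform(6, 18), rng.uniform(1, 3), ang)
            shade = rng.uniform(-25, 25)
            img[y0:y0 + mask.shape[0], x0:x0 + mask.shape[1]][mask] += shade
    else:
        if config.striped_background:
            img = np.full((s, s, 3), 225.0)
            stripes = (np.arange(s) // (config.stripe_period // 2)) % 2 == 1
            img[:, stripes] = 170.0                  # gray stripes
        else:
            img = np.full((s, s, 3), 235.0)          # plain white-ish
        img += rng.normal(0, 4, size=(s, s, 3))
    return img


def render_field(count: int, config: SynthConfig,
                 rng: np.random.Generator | None = None) -> ImageSample:
    """Render exactly `count` object instances; raises CapacityError if they
    cannot be placed under the configured overlap limit."""
    if count < 0:
        raise ValueError("count must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    s = config.image_size
    img = _background(config, rng)
    # quick geometric packing bound before any placement attempts
    mean_area = np.pi * (np.mean(config.length_px) / 2) * (np.mean(config.width_px) / 2)
    if count * mean_area * (1.0 - config.occlusion) > 0.9 * s * s:
        raise CapacityError(
            f"count {count} exceeds the packing capacity of a {s}x{s} image")
    occupied = np.zeros((s, s), dtype=bool)
    margin = max(config.length_px) / 2
    positions: list[tuple[float, float, float, float, float]] = []
    if config.mode == "ear_field":
        base_color = np.array([196.0, 172.0, 96.0])  # ripe golden
    else:
        base_color = np.array([190.0, 150.0, 92.0])  # grain tan
    for _ in range(count):
        placed = False
        for _attempt in range(300):
            cx = rng.uniform(margin, s - margin)
            cy = rng.uniform(margin, s - margin)
            ang = rng.uniform(0, np.pi)
            length = rng.uniform(*config.length_px)
            width = rng.uniform(*config.width_px)
            mask, (y0, x0) = _ellipse_mask(s, s, cx, cy, length / 2, width / 2, ang)
            region = occupied[y0:y0 + mask.shape[0], x0:x0 + mask.shape[1]]
            overlap = (mask & region).sum() / max(1, mask.sum())
            if overlap > config.occlusion:
                continue
            jitter = 1.0 + config.color_jitter * rng.uniform(-1, 1, 3)
            patch = img[y0:y0 + mask.shape[0], x0:x0 + mask.shape[1]]
            patch[mask] = base_color * jitter
            if config.mode == "ear_field":
                # awn-like speckle texture along the ear
                speckle = rng.normal(0, 18, size=(mask.sum(), 3))
                patch[mask] = np.clip(patch[mask] + speckle, 0, 255)
            else:
                shade = rng.normal(0, 8, size=(mask.sum(), 3))
                patch[mask] = np.clip(patch[mask] + shade, 0, 255)
            # dilate by one pixel so occlusion=0 guarantees disjoint components
            region |= ndimage.binary_dilation(mask)
            positions.append((cx, cy, ang, length, width))
            placed = True
            break
        if not placed:
            raise CapacityError(
                f"could not place instance {len(positions) + 1} of {count} "
                f"within the overlap limit {config.occlusion}")
    return ImageSample(image=np.clip(img, 0, 255).astype(np.uint8),
                       count=count, positions=positions)


def generate_sample(config: SynthConfig, seed_seq: np.random.SeedSequence,
                    force_count: int | None = None) -> ImageSample:
    """One fully seeded sample: count draw then rendering from one stream."""
    rng = np.random.default_rng(seed_seq)
    count = force_count if force_count is not None else sample_count(config, rng)
    return render_field(count, config, rng)


def generate_dataset(n: int, config: SynthConfig, outdir: str | Path,
                     n_negatives: int = 0) -> pd.DataFrame:
    """Write `n` PNG images plus a `manifest.csv` (header ``image,count``)
    and a debug sidecar `positions.csv`; returns the manifest frame.

    ``n_negatives`` of the n images are forced to count 0 (background-only
    negative samples, rendered first).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqs = np.random.SeedSequence(config.seed).spawn(n)
    rows, sidecar = [], []
    for i, sq in enumerate(seqs):
        sample = generate_sample(config, sq,
                                 force_count=0 if i < n_negatives else None)
        name = f"img_{i:05d}.png"
        Image.fromarray(sample.image).save(outdir / name)
        rows.append({"image": name, "count": sample.count})
        for (x, y, ang, ln, wd) in sample.positions:
            sidecar.append({"image": name, "x": round(x, 2), "y": round(y, 2),
                            "angle": round(ang, 4), "len": round(ln, 2),
                            "width": round(wd, 2)})
    manifest = pd.DataFrame(rows, columns=["image", "count"])
    manifest.to_csv(outdir / "manifest.csv", index=False)
    pd.DataFrame(sidecar, columns=["image", "x", "y", "angle", "len", "width"]
                 ).to_csv(outdir / "positions.csv", index=False)
    return manifest


def split_manifest(manifest: pd.DataFrame, seed: int,
                   fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Disjoint train/val/test partition by seeded shuffle."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    idx = np.random.default_rng(seed).permutation(len(manifest))
    n_train = int(round(fractions[0] * len(manifest)))
    n_val = int(round(fractions[1] * len(manifest)))
    parts = (idx[:n_train], idx[n_train:n_train + n_val], idx[n_train + n_val:])
    return tuple(manifest.iloc[p].reset_index(drop=True) for p in parts)
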