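"""Dataset I/O: count manifests, box-annotation reduction, preprocessing.

Supports two on-disk layouts: the package's own ``image,count`` CSV manifest,
and detection-style annotation CSVs (as distributed with the public wheat
head datasets) whose per-image box strings are reduced to bare counts —
the network is count-supervised and never consumes box geometry.

Images are uniformly rescaled to a square network input (default 512 x 512,
bilinear) and channel-normalised; counts are resize-invariant so labels
need no adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

NO_BOX_SENTINEL = "no_box"


class BoxParseError(ValueError):
    """A box token in an annotation string could not be parsed."""


@dataclass(frozen=True)
class PreprocessSpec:
    """Target side, per-channel normalisation and interpolation mode."""

    size: int = 512
    mean: tuple[float, float, float] = IMAGENET_MEAN
    std: tuple[float, float, float] = IMAGENET_STD
    interpolation: str = "bilinear"

    @classmethod
    def identity(cls, size: int = 512) -> "PreprocessSpec":
        """No normalisation beyond the [0, 1] scaling — for from-scratch runs."""
        return cls(size=size, mean=(0.0, 0.0, 0.0), std=(1.0, 1.0, 1.0))


@dataclass(frozen=True)
class SampleRef:
    """A count-labelled image on disk."""

    path: Path
    count: int


def parse_boxes_string(s: str) -> int:
    """Number of boxes in a semicolon-separated annotation string.

    Boxes are four space-separated numbers; the sentinel ``no_box`` (or an
    empty/whitespace string) means zero boxes.
    """
    s = s.strip()
    if not s or s == NO_BOX_SENTINEL:
        return 0
    count = 0
    for token in s.split(";"):
        parts = token.split()
        if len(parts) != 4:
            raise BoxParseError(
                f"box token {token.strip()!r} has {len(parts)} fields, expected 4")
        for p in parts:
            try:
                float(p)
            except ValueError:
                raise BoxParseError(
                    f"non-numeric value {p!r} in box token {token.strip()!r}"
                ) from None
        count += 1
    return count


def load_manifest(path: str | Path) -> list[SampleRef]:
    """Read an ``image,count`` CSV; image paths resolve relative to the CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"image", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    refs = []
    for row in df.itertuples(index=False):
        count = int(row.count)
        if count < 0:
            raise ValueError(f"negative count {count} for image {row.image}")
        img = path.parent / str(row.image)
        if not img.exists():
            raise FileNotFoundError(f"image listed in manifest not found: {img}")
        refs.append(SampleRef(path=img, count=count))
    return refs


def gwhd_to_manifest(annotation_csv: str | Path,
                     image_column: str = "image_name",
                     boxes_column: str = "BoxesString") -> pd.DataFrame:
    """Reduce a detection-style annotation CSV to an ``image,count`` frame."""
    df = pd.read_csv(annotation_csv)
    counts = [parse_boxes_string(str(s)) for s in df[boxes_column].fillna("")]
    return pd.DataFrame({"image": df[image_column], "count": counts})


def preprocess(image: np.ndarray | Image.Image | str | Path,
               spec: PreprocessSpec | None = None) -> np.ndarray:
    """Image -> float32 (3, S, S): resize, scale to [0, 1], normalise."""
    spec = spec or PreprocessSpec()
    if isinstance(image, (str, Path)):
        image = Image.open(image)
    if isinstance(image, np.ndarray):
        image = Image.fromarray(image)
    image = image.convert("RGB")
    resample = {"bilinear": Image.BILINEAR, "nearest": Image.NEAREST,
                "bicubic": Image.BICUBIC}[spec.interpolation]
    image = image.resize((spec.size, spec.size), resample=resample)
    arr = np.asarray(image, dtype=np.float32) / 255.0       # (S, S, 3)
    mean = np.asarray(spec.mean, dtype=np.float32)
    std = np.asarray(spec.std, dtype=np.float32)
    arr = (arr - mean) / std
    return np.ascontiguousarray(arr.transpose(2, 0, 1))


def load_arrays(refs: list[SampleRef],
                spec: PreprocessSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Materialise a manifest as (images (N,3,S,S), counts (N,)) arrays."""
    spec = spec or PreprocessSpec()
    images = np.stack([preprocess(r.path, spec) for r in refs])
    counts = np.array([r.count for r in refs], dtype=np.float32)
    return images, counts
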