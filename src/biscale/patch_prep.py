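"""Slide tiling, tissue filtering, spot cropping and patch embedding.

Slides are assumed to be RGB rasters already resampled to 20x magnification
(0.5 um/pixel); no pyramidal WSI decoding is performed here.  Tiling emits
the full non-overlapping grid of patch_size squares ordered x-major by
(x, y) origin; patches with less than 15% tissue coverage are discarded and
slides keep only if strictly more than ``min_tiles`` tiles survive.  Spot
patches are cropped centered on the spot pixel coordinate, shifted inward
at borders.  Embedding goes through a pluggable encoder; a deterministic
synthetic encoder (seeded random projection of per-channel patch summary
statistics) stands in for external pathology foundation models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

DEFAULT_PATCH_SIZE = 256
#: minimum fraction of tissue pixels for a patch to be kept (strict "<" discards)
MIN_TISSUE_COVERAGE = 0.15
#: a slide is kept only if strictly more than this many tiles survive filtering
MIN_TILES_PER_SLIDE = 1000
#: a pixel counts as tissue when its darkest channel is below this (8-bit);
#: excludes near-white background — a stand-in for any segmentation method
TISSUE_PIXEL_THRESHOLD = 220
DEFAULT_EMBED_DIM = 512


@dataclass
class PatchSequence:
    """An ordered per-slide sequence of patch embeddings."""

    embeddings: np.ndarray           # n x d
    coords: np.ndarray               # n x 2 integer pixel origins (x, y)
    patch_size: int
    level_tag: str                   # 'bulk_tile' | 'spot_patch'
    slide_id: str
    ordering: str = "x_major"        # recorded: the recurrence is order-sensitive
    shifted: np.ndarray | None = None  # spot crops moved inward at borders

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        if len(self.embeddings) != len(self.coords):
            raise ValueError("one coordinate per embedding is required")
        if not np.all(np.isfinite(self.embeddings)):
            raise ValueError("embeddings must be finite")

    @property
    def n(self) -> int:
        return len(self.coords)

    @property
    def d(self) -> int:
        return self.embeddings.shape[1]


@dataclass
class EncoderSpec:
    """Pluggable patch encoder: RGB patch -> d-vector, deterministic."""

    name: str
    dim: int
    fn: Callable[[np.ndarray], np.ndarray]

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        return np.asarray(self.fn(patch), dtype=float)


def _as_rgb(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB raster, got shape {arr.shape}")
    return arr


def tile_slide(image, patch_size: int = DEFAULT_PATCH_SIZE):
    """Non-overlapping patch grid, ordered lexicographically by (x, y) origin.

    Partial border patches are dropped.  Returns a list of ((x, y), patch)
    with x = column and y = row of the top-left corner, 0-based.
    """
    arr = _as_rgb(image)
    h, w = arr.shape[:2]
    if h < patch_size or w < patch_size:
        raise ValueError(f"image {w}x{h} smaller than one {patch_size}px patch")
    out = []
    for x in range(0, w - patch_size + 1, patch_size):
        for y in range(0, h - patch_size + 1, patch_size):
            out.append(((x, y), arr[y:y + patch_size, x:x + patch_size]))
    return out


def tissue_coverage(patch: np.ndarray) -> float:
    """Fraction of pixels whose darkest channel is below the background
    threshold (near-white pixels count as background)."""
    arr = _as_rgb(patch)
    tissue = arr.min(axis=2) < TISSUE_PIXEL_THRESHOLD
    return float(tissue.mean())


def filter_patches(patches, min_coverage: float = MIN_TISSUE_COVERAGE):
    """Drop patches with coverage strictly below ``min_coverage``;
    order is preserved.  ``patches`` is a list of ((x, y), patch)."""
    return [(c, p) for c, p in patches if tissue_coverage(p) >= min_coverage]


def slide_qc(seq: PatchSequence, min_tiles: int = MIN_TILES_PER_SLIDE) -> bool:
    """Keep a slide only when strictly more than ``min_tiles`` tiles remain."""
    return seq.n > min_tiles


def crop_spot_patch(image, center: tuple[int, int],
                    size: int = DEFAULT_PATCH_SIZE):
    """A size x size crop centered on a spot pixel coordinate.

    Near borders the window is shifted inward so it fits entirely within
    the image (no padding with fabricated pixels); the shift is reported.
    Returns (patch, (origin_x, origin_y), shifted).
    """
    arr = _as_rgb(image)
    h, w = arr.shape[:2]
    cx, cy = int(center[0]), int(center[1])
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"spot center {center} lies outside the {w}x{h} image")
    if w < size or h < size:
        raise ValueError(f"image {w}x{h} smaller than one {size}px patch")
    ox, oy = cx - size // 2, cy - size // 2
    ox_c = min(max(ox, 0), w - size)
    oy_c = min(max(oy, 0), h - size)
    shifted = (ox_c != ox) or (oy_c != oy)
    return arr[oy_c:oy_c + size, ox_c:ox_c + size], (ox_c, oy_c), shifted


def embed_patches(patches, encoder: EncoderSpec, slide_id: str = "",
                  level_tag: str = "bulk_tile",
                  patch_size: int = DEFAULT_PATCH_SIZE) -> PatchSequence:
    """Embed an ordered list of ((x, y), patch) through the encoder."""
    coords, rows = [], []
    for i, (c, p) in enumerate(patches):
        v = encoder(p)
        if v.shape != (encoder.dim,):
            raise ValueError(
                f"encoder returned shape {v.shape}, expected ({encoder.dim},)")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite embedding for patch {i} at {c}")
        coords.append(c)
        rows.append(v)
    return PatchSequence(np.vstack(rows), np.asarray(coords), patch_size,
                         level_tag, slide_id)


def synthetic_encoder(dim: int = DEFAULT_EMBED_DIM, seed: int = 0) -> EncoderSpec:
    """Deterministic stand-in encoder: a fixed seeded random projection of
    per-channel mean/std/min/max patch statistics.

    Identical patches map to bitwise-identical embeddings, which is all the
    downstream pipeline requires of an encoder.
    """
    rng = np.random.default_rng(seed)
    proj = rng.normal(size=(dim, 12)) / np.sqrt(12)
    bias = rng.normal(size=dim) * 0.01

    def fn(patch: np.ndarray) -> np.ndarray:
        arr = _as_rgb(patch).astype(float) / 255.0
        feats = np.concatenate([
            arr.mean(axis=(0, 1)), arr.std(axis=(0, 1)),
            arr.min(axis=(0, 1)), arr.max(axis=(0, 1)),
        ])
        return proj @ feats + bias

    return EncoderSpec(name=f"synthetic-rp-{seed}", dim=dim, fn=fn)
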