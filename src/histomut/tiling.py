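"""Tile the tumor region of a slide into non-overlapping fixed-size windows.

Windows are laid on the grid of multiples of the tile size (origin top-left);
partial edge windows are discarded rather than padded.  A window is kept iff
its background fraction is at most ``bg_max`` and its tumor-mask fraction is
at least ``tumor_min``.

Background pixels are defined by an HSV rule: low saturation and high value
(near-white glass).  Pale eosin-stained tissue is saturated enough to survive
the rule; the thresholds are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import laplace
from skimage.color import rgb2hsv

from .io import SlideRecord

logger = logging.getLogger("histomut")

#: HSV thresholds for the background (white glass) rule.
BG_SATURATION_MAX = 0.15
BG_VALUE_MIN = 0.82


@dataclass
class Tile:
    """A size×size window of a slide at grid origin (x0, y0) = (col, row)."""

    slide_id: str
    x0: int
    y0: int
    size: int
    pixels: np.ndarray  # (size, size, 3) uint8
    background_fraction: float
    tumor_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_fraction <= 1.0):
            raise ValueError("background_fraction outside [0, 1]")
        if not (0.0 <= self.tumor_fraction <= 1.0):
            raise ValueError("tumor_fraction outside [0, 1]")


def background_mask(pixels: np.ndarray,
                    saturation_max: float = BG_SATURATION_MAX,
                    value_min: float = BG_VALUE_MIN) -> np.ndarray:
    """Boolean mask of background (near-white, low-saturation) pixels."""
    pixels = np.asarray(pixels)
    if pixels.size == 0:
        raise ValueError("empty raster")
    hsv = rgb2hsv(pixels.astype(np.float64) / 255.0
                  if pixels.dtype != np.float64 else pixels)
    return (hsv[..., 1] < saturation_max) & (hsv[..., 2] > value_min)


def background_fraction(tile_pixels: np.ndarray,
                        saturation_max: float = BG_SATURATION_MAX,
                        value_min: float = BG_VALUE_MIN) -> float:
    """Fraction of pixels classified as background by the HSV rule."""
    return float(background_mask(tile_pixels, saturation_max, value_min).mean())


def noise_ratio(slide_image: np.ndarray,
                blur_threshold: float | None = None,
                blur_block: int = 64,
                saturation_max: float = BG_SATURATION_MAX,
                value_min: float = BG_VALUE_MIN) -> float:
    """(blank area + blurred area) / total area of a slide image.

    Blank pixels follow the background rule.  Blur is measured per
    ``blur_block``-sized block as the variance of a 3×3 Laplacian of the gray
    image; a block below ``blur_threshold`` counts as blurred unless it is
    already blank.  ``blur_threshold=None`` disables the blur term.
    """
    img = np.asarray(slide_image)
    if img.size == 0:
        raise ValueError("empty raster")
    blank = background_mask(img, saturation_max, value_min)
    total = blank.size
    n_noise = int(blank.sum())

    if blur_threshold is not None:
        gray = img.astype(np.float64).mean(axis=-1) / 255.0
        lap = laplace(gray)
        h, w = gray.shape
        for r in range(0, h - blur_block + 1, blur_block):
            for c in range(0, w - blur_block + 1, blur_block):
                block = (slice(r, r + blur_block), slice(c, c + blur_block))
                if float(lap[block].var()) < blur_threshold:
                    n_noise += int((~blank[block]).sum())
    return n_noise / total


def tile_slide(slide: SlideRecord, size: int = 512,
               bg_max: float = 0.75, tumor_min: float = 0.5,
               saturation_max: float = BG_SATURATION_MAX,
               value_min: float = BG_VALUE_MIN) -> list[Tile]:
    """Cut the slide into kept tiles on the non-overlapping grid (row-major)."""
    report = tiling_report(slide, size, bg_max, tumor_min,
                           saturation_max, value_min)
    tiles = []
    for row in report.itertuples():
        if row.kept:
            y0, x0 = int(row.y0), int(row.x0)
            tiles.append(Tile(
                slide_id=slide.slide_id, x0=x0, y0=y0, size=size,
                pixels=slide.image[y0:y0 + size, x0:x0 + size],
                background_fraction=row.background_fraction,
                tumor_fraction=row.tumor_fraction,
            ))
    return tiles


def tiling_report(slide: SlideRecord, size: int = 512,
                  bg_max: float = 0.75, tumor_min: float = 0.5,
                  saturation_max: float = BG_SATURATION_MAX,
                  value_min: float = BG_VALUE_MIN) -> pd.DataFrame:
    """Per-window statistics for every full grid window of a slide.

    Columns: slide_id, x0, y0, background_fraction, tumor_fraction, kept.
    Row order is row-major over window origins.
    """
    if size < 8:
        raise ValueError(f"tile size must be >= 8, got {size}")
    if not (0.0 <= bg_max <= 1.0):
        raise ValueError(f"bg_max must lie in [0, 1], got {bg_max}")
    if not (0.0 <= tumor_min <= 1.0):
        raise ValueError(f"tumor_min must lie in [0, 1], got {tumor_min}")

    h, w = slide.shape
    if h < size or w < size:
        logger.warning("slide %s (%dx%d) smaller than tile size %d; no tiles",
                       slide.slide_id, h, w, size)

    bg = background_mask(slide.image, saturation_max, value_min)
    rows = []
    for y0 in range(0, h - size + 1, size):
        for x0 in range(0, w - size + 1, size):
            win = (slice(y0, y0 + size), slice(x0, x0 + size))
            bgf = float(bg[win].mean())
            tf = float(slide.tumor_mask[win].mean())
            rows.append({
                "slide_id": slide.slide_id, "x0": x0, "y0": y0,
                "background_fraction": bgf, "tumor_fraction": tf,
                "kept": bool(bgf <= bg_max and tf >= tumor_min),
            })
    return pd.DataFrame(
        rows, columns=["slide_id", "x0", "y0", "background_fraction",
                       "tumor_fraction", "kept"],
    )
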