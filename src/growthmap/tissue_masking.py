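"""Low-magnification tissue localization and tile-grid filtering.

Tissue appears dark against the bright optical background of a scanned
slide, so foreground is found by thresholding a gray-level rendering at low
magnification (~5x), then cleaned up by hole filling and morphological
closing.  Tiles with insufficient tissue are dropped before classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, footprint_rectangle

from .slide_io import SlideImage, TileGrid

__all__ = ["TissueMask", "luma", "compute_tissue_mask", "filter_tiles"]

#: Rec. 601 luma weights used for the gray-level conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class TissueMask:
    """Binary tissue-foreground raster at a coarse pyramid level.

    ``downsample`` is level-0 pixels per mask pixel.  ``threshold`` is the
    gray-level cutoff that produced the mask (foreground where gray < t).
    """

    mask: np.ndarray  # (H, W) bool
    downsample: int
    threshold: float = 230.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not 0 <= self.threshold <= 255:
            raise ValueError("threshold must be in [0, 255]")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")


def luma(rgb: np.ndarray) -> np.ndarray:
    """Gray-level conversion of an 8-bit RGB raster (Rec. 601 weights)."""
    return rgb[..., :3].astype(float) @ LUMA_WEIGHTS


def compute_tissue_mask(
    slide: SlideImage,
    threshold: float = 230.0,
    target_magnification: float = 5.0,
    closing_size: int = 5,
) -> TissueMask:
    """Locate tissue foreground at ~``target_magnification``.

    Foreground is ``gray < threshold``; enclosed background pockets are then
    filled and the mask is closed with a square structuring element
    (default 5x5) to bridge small gaps.
    """
    desired = max(1.0, slide.magnification / target_magnification)
    level = slide.level_for_downsample(desired)
    raster = slide.levels[level]
    fg = luma(raster) < threshold
    fg = ndimage.binary_fill_holes(fg)
    if closing_size > 1:
        fg = closing(fg, footprint_rectangle((closing_size, closing_size)))
    return TissueMask(fg, slide.downsamples[level], threshold)


def tissue_fraction(tile_xy: tuple[int, int], tile_px: int, mask: TissueMask) -> float:
    """Fraction of a tile's footprint covered by mask foreground.

    Computed over the mask pixels whose centers fall inside the tile's
    level-0 footprint.
    """
    x, y = tile_xy
    d = mask.downsample
    # mask pixel i has center (i + 0.5) * d; centers in [y, y + tile_px)
    i0 = int(np.ceil(y / d - 0.5))
    i1 = int(np.ceil((y + tile_px) / d - 0.5))
    j0 = int(np.ceil(x / d - 0.5))
    j1 = int(np.ceil((x + tile_px) / d - 0.5))
    i0, j0 = max(i0, 0), max(j0, 0)
    i1 = min(i1, mask.mask.shape[0])
    j1 = min(j1, mask.mask.shape[1])
    if i1 <= i0 or j1 <= j0:
        return 0.0
    window = mask.mask[i0:i1, j0:j1]
    return float(window.mean())


def filter_tiles(
    grid: TileGrid,
    mask: TissueMask,
    min_tissue_fraction: float = 0.20,
) -> TileGrid:
    """Retain tiles whose tissue-foreground fraction is >= the cutoff.

    The boundary is inclusive: a tile at exactly the cutoff is kept; only
    tiles strictly below it are deleted.
    """
    if not 0 < min_tissue_fraction <= 1:
        raise ValueError("min_tissue_fraction must be in (0, 1]")
    expected_h = int(np.ceil(grid.slide_height / mask.downsample))
    if abs(mask.mask.shape[0] - expected_h) > 1:
        raise ValueError("tissue mask and tile grid refer to different slides")
    kept = [
        xy
        for xy in grid.tiles
        if tissue_fraction(xy, grid.tile_px, mask) >= min_tissue_fraction
    ]
    return TileGrid(grid.tile_px, kept, grid.slide_width, grid.slide_height)
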