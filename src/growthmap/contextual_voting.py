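"""Contextual soft-voting classification of slide tiles.

Each retained tile is classified together with eight overlapping
"glimpses" obtained by shifting the central tile by one third of its edge
length horizontally, vertically and diagonally.  The nine probability
vectors are combined by weighted soft voting,

    y_hat = argmax_i  sum_j  a_j * p_ij,

with uniform weights and N = 9 by default, and the winning class is
assigned to the central tile.  The combination is permutation invariant;
glimpses falling outside the slide are dropped (N shrinks) rather than
padded with fabricated tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classes import ALL_CLASSES, BACKGROUND, GrowthPattern
from .classifier import TileClassifier, check_probabilities, classify_batch
from .slide_io import SlideImage, TileGrid
from .stain_color import ColorPattern, normalize_tile
from .tumor_map import TumorMap

__all__ = ["SoftVoteConfig", "glimpse_coords", "soft_vote", "classify_slide"]


@dataclass
class SoftVoteConfig:
    """Neighborhood and weighting of the soft vote.

    ``weights`` has one entry per glimpse in coordinate order (central
    first); when border glimpses are dropped the weight list is truncated
    to match.  ``shift_fraction`` is the glimpse offset as a fraction of
    the tile edge.
    """

    n_neighborhood: int = 9
    weights: np.ndarray = field(default_factory=lambda: np.ones(9))
    shift_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.n_neighborhood < 1:
            raise ValueError("neighborhood size must be >= 1")
        if len(self.weights) != self.n_neighborhood:
            raise ValueError("weights length must equal neighborhood size")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if not 0 < self.shift_fraction < 1:
            raise ValueError("shift_fraction must be in (0, 1)")


#: Glimpse offset multipliers in fixed order: central first, then the 8
#: neighbors row-major.
_OFFSETS = [(0, 0)] + [
    (dx, dy) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dx, dy) != (0, 0)
]


def glimpse_coords(
    tile_xy: tuple[int, int],
    tile_px: int,
    slide_bounds: tuple[int, int],
    cfg: SoftVoteConfig | None = None,
) -> list[tuple[int, int]]:
    """Top-left coordinates of the central tile and its in-bounds glimpses.

    The shift is ``round(shift_fraction * tile_px)`` level-0 pixels.
    Glimpses extending beyond the slide are dropped; the central tile is
    always first and must itself be in bounds.
    """
    cfg = cfg or SoftVoteConfig()
    x, y = tile_xy
    w, h = slide_bounds
    if x < 0 or y < 0 or x + tile_px > w or y + tile_px > h:
        raise ValueError(f"central tile ({x},{y}) out of slide bounds")
    s = round(cfg.shift_fraction * tile_px)
    coords = []
    for dx, dy in _OFFSETS:
        gx, gy = x + dx * s, y + dy * s
        if 0 <= gx and 0 <= gy and gx + tile_px <= w and gy + tile_px <= h:
            coords.append((gx, gy))
    # a smaller configured neighborhood truncates in coordinate order
    # (central first), e.g. N=1 is central-tile-only classification
    return coords[: cfg.n_neighborhood]


def soft_vote(
    prob_vectors: np.ndarray,
    cfg: SoftVoteConfig | None = None,
) -> GrowthPattern:
    """Weighted soft vote over glimpse probability vectors.

    Ties are broken deterministically toward the lowest class index
    (enum order AC < MP < SO < CR < NT).
    """
    cfg = cfg or SoftVoteConfig()
    p = check_probabilities(prob_vectors)
    if len(p) == 0:
        raise ValueError("soft_vote requires at least one probability vector")
    if len(p) > cfg.n_neighborhood:
        raise ValueError("more probability vectors than the neighborhood size")
    w = cfg.weights[: len(p)]
    scores = w @ p
    return ALL_CLASSES[int(np.argmax(scores))]


def classify_slide(
    slide: SlideImage,
    grid: TileGrid,
    model: TileClassifier,
    target_pattern: ColorPattern | None = None,
    cfg: SoftVoteConfig | None = None,
) -> TumorMap:
    """Soft-vote classify every retained tile of a slide into a tumor map.

    ``grid`` is the tissue-filtered tile grid; grid positions that were
    filtered out stay background in the map.  Each glimpse raster is
    optionally Reinhard-normalized to ``target_pattern`` and classified
    independently; the vote is assigned to the central tile.  Deterministic
    for a fixed model state.
    """
    cfg = cfg or SoftVoteConfig()
    ny, nx = grid.shape
    labels = np.full((ny, nx), BACKGROUND, dtype=np.uint8)
    bounds = (slide.width_px, slide.height_px)

    # Gather all glimpse rasters for one batched classification pass.
    rasters: list[np.ndarray] = []
    spans: list[tuple[int, int, int]] = []  # (row, col, n_glimpses)
    for x, y in grid.tiles:
        coords = glimpse_coords((x, y), grid.tile_px, bounds, cfg)
        for gx, gy in coords:
            raster = slide.read_region(gx, gy, grid.tile_px, grid.tile_px)
            if target_pattern is not None:
                raster = normalize_tile(raster, target_pattern)
            rasters.append(raster)
        spans.append((y // grid.tile_px, x // grid.tile_px, len(coords)))

    probs = classify_batch(rasters, model)
    pos = 0
    for row, col, n in spans:
        labels[row, col] = int(soft_vote(probs[pos : pos + n], cfg))
        pos += n
    return TumorMap(labels=labels, tile_px=grid.tile_px, slide_id=slide.slide_id)
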