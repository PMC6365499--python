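"""Tumor maps: per-tile class-label grids, quantification and rendering.

A tumor map assigns one of the five tissue classes (or background) to each
cell of a slide's tile grid.  Growth-pattern composition is quantified as
tile-count percentages — tiles are equal-area, so counts are area
fractions at map resolution — optionally rounded to 5% increments the way
pathologists report pattern composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
import warnings

import numpy as np

from .classes import ALL_CLASSES, BACKGROUND, TUMOR_CLASSES, GrowthPattern
from .slide_io import SlideImage

__all__ = ["TumorMap", "class_percentages", "round_to_increment", "render_overlay",
           "save_map", "load_map", "CLASS_PALETTE"]

#: Fixed rendering palette (hex): AC blue, MP orange, SO red, CR purple,
#: NT green.
CLASS_PALETTE = {
    GrowthPattern.AC: "#1f77b4",
    GrowthPattern.MP: "#ff7f0e",
    GrowthPattern.SO: "#d62728",
    GrowthPattern.CR: "#9467bd",
    GrowthPattern.NT: "#2ca02c",
}


@dataclass
class TumorMap:
    """Per-tile classification result aligned to a slide's tile grid."""

    labels: np.ndarray  # (rows, cols) uint8; 0 = background
    tile_px: int
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.max(initial=0) > 5:
            raise ValueError("map codes must be in 0..5")
        if self.tile_px <= 0:
            raise ValueError("tile_px must be positive")

    @property
    def counts(self) -> dict[GrowthPattern, int]:
        """Per-class tile counts (background excluded)."""
        return {c: int((self.labels == int(c)).sum()) for c in ALL_CLASSES}

    @property
    def n_tissue_tiles(self) -> int:
        return int((self.labels != BACKGROUND).sum())


def round_to_increment(fractions: np.ndarray, increment: float = 5.0) -> np.ndarray:
    """Round percentages to an increment with largest-remainder correction
    so they still sum to 100."""
    fractions = np.asarray(fractions, dtype=float)
    units = fractions / increment
    floors = np.floor(units)
    remainder = int(round(100.0 / increment - floors.sum()))
    order = np.argsort(-(units - floors), kind="stable")
    out = floors.copy()
    for i in range(remainder):
        out[order[i % len(out)]] += 1
    return out * increment


def class_percentages(tmap: TumorMap, round_to_5: bool = False) -> dict:
    """Quantify map composition.

    Returns ``{"tissue": {class: %}, "tumor": {class: %}}`` where "tissue"
    percentages are relative to all classified tiles and "tumor"
    percentages are relative to tumor tiles only (the form in which growth
    pattern composition is reported clinically, optionally in 5%
    increments).  An all-background map yields empty summaries with a
    warning.
    """
    n_tissue = tmap.n_tissue_tiles
    if n_tissue == 0:
        warnings.warn("tumor map has no classified tiles; empty summary")
        return {"tissue": {}, "tumor": {}}
    counts = tmap.counts
    tissue = {c: 100.0 * counts[c] / n_tissue for c in ALL_CLASSES}
    n_tumor = sum(counts[c] for c in TUMOR_CLASSES)
    tumor: dict[GrowthPattern, float] = {}
    if n_tumor > 0:
        vals = np.array([100.0 * counts[c] / n_tumor for c in TUMOR_CLASSES])
        if round_to_5:
            vals = round_to_increment(vals, 5.0)
        tumor = dict(zip(TUMOR_CLASSES, vals.tolist()))
    return {"tissue": tissue, "tumor": tumor}


def _hex_to_rgb(code: str) -> np.ndarray:
    return np.array([int(code[i : i + 2], 16) for i in (1, 3, 5)], dtype=float)


def render_overlay(
    tmap: TumorMap,
    slide: SlideImage,
    alpha: float = 0.5,
    level: int | None = None,
) -> np.ndarray:
    """Alpha-blend the class-colored map over a slide rendering.

    Background map cells leave the slide unmodified.  ``level`` picks the
    pyramid level to render on (default: coarsest).  Pure function: neither
    the map nor the slide is altered.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    rows, cols = tmap.labels.shape
    if rows != slide.height_px // tmap.tile_px or cols != slide.width_px // tmap.tile_px:
        raise ValueError("tumor map and slide frames do not match")
    if level is None:
        level = len(slide.levels) - 1
    out = slide.levels[level].astype(float).copy()
    d = slide.downsamples[level]
    step = tmap.tile_px / d
    for (r, c), code in np.ndenumerate(tmap.labels):
        if code == BACKGROUND:
            continue
        color = _hex_to_rgb(CLASS_PALETTE[GrowthPattern(code)])
        y0, y1 = round(r * step), round((r + 1) * step)
        x0, x1 = round(c * step), round((c + 1) * step)
        block = out[y0:y1, x0:x1]
        out[y0:y1, x0:x1] = (1 - alpha) * block + alpha * color
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def save_map(tmap: TumorMap, path) -> None:
    payload = {
        "slide_id": tmap.slide_id,
        "tile_px": tmap.tile_px,
        "shape": list(tmap.labels.shape),
        "labels": tmap.labels.ravel().tolist(),
        "counts": {c.name: n for c, n in tmap.counts.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_map(path) -> TumorMap:
    with open(path) as fh:
        payload = json.load(fh)
    labels = np.array(payload["labels"], dtype=np.uint8).reshape(payload["shape"])
    return TumorMap(labels=labels, tile_px=payload["tile_px"], slide_id=payload["slide_id"])
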