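"""Color x orientation augmentation of labeled training tiles.

Growth patterns have no inherent orientation, and H&E hue varies between
laboratories, so each labeled tile is expanded into the product of color
variants (the original plus one Reinhard transfer per target pattern) and
the 8 square symmetries: with 4 color patterns that is (1 + 4) x 8 = 40
variants per tile.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .classes import GrowthPattern, parse_label
from .stain_color import ColorPattern, reinhard_transfer

__all__ = [
    "LabeledTile",
    "orientation_apply",
    "orientation_variants",
    "augment_tile",
    "augment_dataset",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ["path", "label", "source_id", "color_variant", "orientation"]

#: Inverse orientation code for each of the 8 square symmetries.
ORIENTATION_INVERSE = {0: 0, 1: 3, 2: 2, 3: 1, 4: 4, 5: 5, 6: 6, 7: 7}


@dataclass
class LabeledTile:
    """An RGB training tile with its class and variant provenance."""

    raster: np.ndarray
    label: GrowthPattern
    source_id: str = ""
    color_variant: str = "original"
    orientation: int = 0

    def __post_init__(self) -> None:
        if self.orientation not in range(8):
            raise ValueError("orientation code must be in 0..7")
        self.label = GrowthPattern(self.label)


def orientation_apply(raster: np.ndarray, code: int) -> np.ndarray:
    """Apply one of the 8 square symmetries.

    Codes 0-3 are counter-clockwise rotations of the original by
    0/90/180/270 degrees; codes 4-7 are the same rotations of the
    diagonally flipped (transposed) raster.
    """
    if code not in range(8):
        raise ValueError("orientation code must be in 0..7")
    out = raster.swapaxes(0, 1) if code >= 4 else raster
    return np.rot90(out, k=code % 4)


def orientation_variants(raster: np.ndarray) -> list[np.ndarray]:
    """All 8 orientation variants in code order.

    Duplicates arising from symmetric content are still emitted — the
    augmentation factor is fixed by construction, not by content.
    """
    if raster.shape[0] != raster.shape[1]:
        raise ValueError("orientation variants require a square tile")
    return [orientation_apply(raster, code) for code in range(8)]


def augment_tile(tile: LabeledTile, patterns: list[ColorPattern]) -> list[LabeledTile]:
    """Expand one tile into (1 + len(patterns)) x 8 labeled variants."""
    color_versions: list[tuple[str, np.ndarray]] = [("original", tile.raster)]
    for pattern in patterns:
        transferred = reinhard_transfer(tile.raster, pattern.stats)
        color_versions.append((pattern.pattern_id, transferred))
    out: list[LabeledTile] = []
    for variant_id, raster in color_versions:
        for code, oriented in enumerate(orientation_variants(raster)):
            out.append(
                replace(
                    tile,
                    raster=oriented,
                    color_variant=variant_id,
                    orientation=code,
                )
            )
    return out


def augment_dataset(
    manifest: pd.DataFrame,
    patterns: list[ColorPattern],
    out_dir: str | Path | None = None,
    dry_run: bool = False,
) -> pd.DataFrame:
    """Expand a tile manifest by the color x orientation product.

    The input manifest needs columns ``path`` and ``label`` (``source_id``
    optional).  In dry-run mode only the output manifest is produced —
    variant counts can be audited without writing hundreds of thousands of
    files.  Otherwise every variant raster is written as PNG under
    ``out_dir``.  Per-class proportions are preserved exactly because the
    expansion factor ``(1 + len(patterns)) * 8`` is identical for every row.
    """
    if "path" not in manifest.columns or "label" not in manifest.columns:
        raise ValueError("manifest must have 'path' and 'label' columns")
    variant_ids = ["original"] + [p.pattern_id for p in patterns]
    rows = []
    if not dry_run:
        if out_dir is None:
            raise ValueError("out_dir is required unless dry_run=True")
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    for row in manifest.itertuples(index=False):
        label = parse_label(str(row.label)) if isinstance(row.label, str) else GrowthPattern(row.label)
        source_id = getattr(row, "source_id", Path(str(row.path)).stem)
        if dry_run:
            for variant in variant_ids:
                for code in range(8):
                    rows.append((str(row.path), label.name, source_id, variant, code))
            continue
        raster = np.asarray(Image.open(row.path).convert("RGB"))
        tile = LabeledTile(raster, label, source_id=str(source_id))
        for variant in augment_tile(tile, patterns):
            name = f"{variant.source_id}__{variant.color_variant}__o{variant.orientation}.png"
            out_path = Path(out_dir) / name
            Image.fromarray(variant.raster).save(out_path)
            rows.append(
                (str(out_path), label.name, variant.source_id, variant.color_variant, variant.orientation)
            )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
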