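"""Seeded synthetic slides, tiles and annotations for pipeline testing.

Real annotated whole-slide images are large and restricted, so the test
fixtures emulate their *statistical* structure instead of their histology:
five procedurally textured tissue families on a bright optical background,
arranged in annotated rectangular regions, with matching ImageScope-style
annotation XML and tile manifests shaped like a two-cohort training
corpus.

The texture families are feature-separable by construction — element
density, connected-component size and lumina (holes) per component echo,
very loosely, the morphology of the real growth patterns:

* SO (solid): large solid discs — big components, no lumina;
* AC (acinar): annular "glands" — one lumen per component;
* CR (cribriform): large blobs perforated by several lumina;
* MP (micropapillary): small tufts of tiny dots — small components;
* NT (non-tumor): sparse pale elements that stay above the dark-foreground
  threshold of the rule-based classifier but below the bright-background
  threshold of the tissue mask.

Two built-in cohort palettes ("alpha", pink-purple; "beta", darker
blue-purple) emulate inter-laboratory staining variance so that color
pattern derivation and Reinhard normalization have real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import disk

from .classes import ALL_CLASSES, GrowthPattern
from .slide_io import AnnotationRegion, AnnotationSet, SlideImage, write_imagescope_xml

__all__ = [
    "TextureSpec",
    "CohortPalette",
    "COHORT_PALETTES",
    "TABLE_SHAPED_COUNTS",
    "generate_texture",
    "SlideLayout",
    "default_slide_layout",
    "generate_slide",
    "generate_tile_corpus",
]


@dataclass
class CohortPalette:
    """Base colors of one pseudo-cohort's staining style."""

    tumor_fill: tuple[int, int, int]
    pale_fill: tuple[int, int, int]
    background: tuple[int, int, int] = (247, 244, 246)
    jitter: int = 10


COHORT_PALETTES = {
    # pink-purple H&E look
    "alpha": CohortPalette(tumor_fill=(168, 92, 168), pale_fill=(236, 205, 222)),
    # darker blue-purple look
    "beta": CohortPalette(tumor_fill=(96, 66, 148), pale_fill=(208, 214, 238)),
}


@dataclass
class TextureSpec:
    """Parameters of one procedural texture family.

    ``coverage`` is the target fraction of the canvas covered by elements;
    ``radius_range`` bounds element radii in pixels; ``holes_range`` bounds
    the number of lumina punched per element (CR only); ``lumen_radius``
    bounds lumen radii.  Element placement is non-overlapping (rejection
    sampled) so component statistics stay separable.
    """

    label: GrowthPattern
    coverage: float
    radius_range: tuple[int, int]
    holes_range: tuple[int, int] = (0, 0)
    lumen_radius: tuple[int, int] = (3, 5)
    cluster_dots: tuple[int, int] = (0, 0)  # MP: dots per tuft
    dot_radius: tuple[int, int] = (2, 3)

    def __post_init__(self) -> None:
        if not 0 < self.coverage < 1:
            raise ValueError("coverage must be in (0, 1)")
        if self.radius_range[0] > self.radius_range[1] or self.radius_range[0] <= 0:
            raise ValueError("degenerate radius range")


DEFAULT_TEXTURES: dict[GrowthPattern, TextureSpec] = {
    GrowthPattern.SO: TextureSpec(GrowthPattern.SO, coverage=0.42, radius_range=(12, 16)),
    GrowthPattern.AC: TextureSpec(
        GrowthPattern.AC, coverage=0.38, radius_range=(11, 14),
        holes_range=(1, 1), lumen_radius=(4, 6),
    ),
    GrowthPattern.CR: TextureSpec(
        GrowthPattern.CR, coverage=0.45, radius_range=(16, 21),
        holes_range=(3, 5), lumen_radius=(3, 4),
    ),
    GrowthPattern.MP: TextureSpec(
        GrowthPattern.MP, coverage=0.10, radius_range=(8, 10),
        cluster_dots=(3, 6), dot_radius=(2, 3),
    ),
    GrowthPattern.NT: TextureSpec(GrowthPattern.NT, coverage=0.35, radius_range=(7, 11)),
}


def _place_centers(
    shape: tuple[int, int],
    n: int,
    radius_range: tuple[int, int],
    rng: np.random.Generator,
    margin: int = 2,
) -> list[tuple[int, int, int]]:
    """Rejection-sample non-overlapping (row, col, radius) element seats.

    Centers may fall anywhere on the canvas (elements crossing the border
    are clipped, as tiles cropped from real tissue would be).
    """
    placed: list[tuple[int, int, int]] = []
    attempts = 0
    max_attempts = 40 * n + 200
    while len(placed) < n and attempts < max_attempts:
        attempts += 1
        r = int(rng.integers(radius_range[0], radius_range[1] + 1))
        cy = int(rng.integers(0, shape[0]))
        cx = int(rng.integers(0, shape[1]))
        if all((cy - py) ** 2 + (cx - px) ** 2 >= (r + pr + margin) ** 2 for py, px, pr in placed):
            placed.append((cy, cx, r))
    return placed


def _fill_color(base: tuple[int, int, int], jitter: int, rng: np.random.Generator) -> np.ndarray:
    return np.clip(np.array(base) + rng.integers(-jitter, jitter + 1, size=3), 0, 255)


def generate_texture(
    spec: TextureSpec,
    size_px: int,
    seed: int | np.random.Generator = 0,
    palette: CohortPalette | str = "alpha",
) -> np.ndarray:
    """Render one square texture tile; seeded-deterministic."""
    if size_px <= 0:
        raise ValueError("size_px must be positive")
    if isinstance(palette, str):
        palette = COHORT_PALETTES[palette]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    canvas = np.empty((size_px, size_px, 3), dtype=np.uint8)
    canvas[:] = palette.background
    noise = rng.normal(0, 2.0, size=canvas.shape)
    canvas = np.clip(canvas + noise, 0, 255).astype(np.uint8)
    shape = (size_px, size_px)
    label = spec.label

    if label == GrowthPattern.NT:
        mean_area = np.pi * np.mean(spec.radius_range) ** 2
        n = max(1, int(spec.coverage * size_px * size_px / mean_area))
        for cy, cx, r in _place_centers(shape, n, spec.radius_range, rng):
            rr, cc = disk((cy, cx), r, shape=shape)
            canvas[rr, cc] = _fill_color(palette.pale_fill, palette.jitter, rng)
        return canvas

    if label == GrowthPattern.MP:
        # pale stromal under-wash so tufts sit in tissue, not optical glass;
        # keeps the tissue mask happy without adding dark foreground
        wash_spec = replace(
            spec, label=GrowthPattern.NT, coverage=0.35, radius_range=(7, 11)
        )
        canvas = generate_texture(wash_spec, size_px, seed=rng, palette=palette)
        # tufts: small clusters of tiny dots in clear space
        tuft_area = np.pi * np.mean(spec.radius_range) ** 2
        n = max(1, int(spec.coverage * size_px * size_px / (0.35 * tuft_area)))
        for cy, cx, r in _place_centers(shape, n, spec.radius_range, rng, margin=6):
            n_dots = int(rng.integers(spec.cluster_dots[0], spec.cluster_dots[1] + 1))
            for _ in range(n_dots):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0, max(r - spec.dot_radius[1], 1))
                dy, dx = rad * np.sin(ang), rad * np.cos(ang)
                dr = int(rng.integers(spec.dot_radius[0], spec.dot_radius[1] + 1))
                rr, cc = disk((cy + dy, cx + dx), dr, shape=shape)
                canvas[rr, cc] = _fill_color(palette.tumor_fill, palette.jitter, rng)
        return canvas

    mean_area = np.pi * np.mean(spec.radius_range) ** 2
    n = max(1, int(spec.coverage * size_px * size_px / mean_area))
    for cy, cx, r in _place_centers(shape, n, spec.radius_range, rng):
        rr, cc = disk((cy, cx), r, shape=shape)
        canvas[rr, cc] = _fill_color(palette.tumor_fill, palette.jitter, rng)
        if label == GrowthPattern.AC:
            lr = int(rng.integers(spec.lumen_radius[0], spec.lumen_radius[1] + 1))
            lr = min(lr, max(r - 4, 2))
            rr, cc = disk((cy, cx), lr, shape=shape)
            canvas[rr, cc] = palette.background
        elif label == GrowthPattern.CR:
            k = int(rng.integers(spec.holes_range[0], spec.holes_range[1] + 1))
            lumina: list[tuple[float, float, int]] = []
            tries = 0
            while len(lumina) < k and tries < 60:
                tries += 1
                lr = int(rng.integers(spec.lumen_radius[0], spec.lumen_radius[1] + 1))
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0, max(r - lr - 3, 1))
                ly, lx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
                if all(
                    (ly - py) ** 2 + (lx - px) ** 2 >= (lr + pr + 2) ** 2
                    for py, px, pr in lumina
                ):
                    lumina.append((ly, lx, lr))
            for ly, lx, lr in lumina:
                rr, cc = disk((ly, lx), lr, shape=shape)
                canvas[rr, cc] = palette.background
    return canvas


# --------------------------------------------------------------------------
# Slides
# --------------------------------------------------------------------------

@dataclass
class SlideLayout:
    """Rectangular class regions on a bright background.

    ``regions`` maps a level-0 rectangle ``(x, y, w, h)`` to a class.
    Regions must not overlap.
    """

    width: int
    height: int
    regions: list[tuple[tuple[int, int, int, int], GrowthPattern]] = field(default_factory=list)

    def __post_init__(self) -> None:
        rects = [r for r, _ in self.regions]
        for i, (x1, y1, w1, h1) in enumerate(rects):
            if x1 < 0 or y1 < 0 or x1 + w1 > self.width or y1 + h1 > self.height:
                raise ValueError("layout region exceeds slide bounds")
            for x2, y2, w2, h2 in rects[i + 1 :]:
                if x1 < x2 + w2 and x2 < x1 + w1 and y1 < y2 + h2 and y2 < y1 + h1:
                    raise ValueError("layout regions overlap")


def default_slide_layout(
    tile_px: int = 120,
    region_tiles: int = 3,
    seed: int = 0,
) -> SlideLayout:
    """One region per class, each ``region_tiles`` x ``region_tiles`` tiles,
    on a tile-aligned grid with one-tile gaps (so glimpses from one region
    never reach another) and a seeded class-to-position assignment."""
    rng = np.random.default_rng(seed)
    rw = region_tiles * tile_px
    cols, rows = 3, 2
    width = tile_px * (cols * region_tiles + cols + 1)
    height = tile_px * (rows * region_tiles + rows + 1)
    cells = [(c, r) for r in range(rows) for c in range(cols)]
    order = rng.permutation(len(cells))[: len(ALL_CLASSES)]
    regions = []
    for cls, cell_idx in zip(ALL_CLASSES, order):
        c, r = cells[cell_idx]
        x = tile_px * (1 + c * (region_tiles + 1))
        y = tile_px * (1 + r * (region_tiles + 1))
        regions.append(((x, y, rw, rw), cls))
    return SlideLayout(width, height, regions)


def generate_slide(
    layout: SlideLayout,
    seed: int = 0,
    palette: CohortPalette | str = "alpha",
    textures: dict[GrowthPattern, TextureSpec] | None = None,
    pixel_size_um: float = 0.5,
    out_dir: str | Path | None = None,
    slide_id: str = "synthetic",
) -> tuple[SlideImage, AnnotationSet]:
    """Compose textures into an annotated synthetic slide.

    Returns the slide (with a synthesized coarse level for tissue masking)
    and its annotation set; when ``out_dir`` is given, also writes
    ``<slide_id>.png`` and matching ImageScope-style ``<slide_id>.xml``
    whose region polygons equal the layout rectangles.
    """
    if isinstance(palette, str):
        palette = COHORT_PALETTES[palette]
    textures = textures or DEFAULT_TEXTURES
    rng = np.random.default_rng(seed)
    canvas = np.empty((layout.height, layout.width, 3), dtype=np.uint8)
    canvas[:] = palette.background
    noise = rng.normal(0, 2.0, size=canvas.shape)
    canvas = np.clip(canvas + noise, 0, 255).astype(np.uint8)
    regions = []
    for (x, y, w, h), cls in layout.regions:
        spec = textures[cls]
        patch = generate_texture(spec, max(w, h), seed=rng, palette=palette)
        canvas[y : y + h, x : x + w] = patch[:h, :w]
        verts = np.array([(x, y), (x + w, y), (x + w, y + h), (x, y + h)], dtype=float)
        regions.append(AnnotationRegion(verts, cls))
    ann = AnnotationSet(regions)
    magnification = 10.0 / pixel_size_um
    from .slide_io import _synthesized_levels  # single-source pyramid logic

    levels, downs = _synthesized_levels(canvas, magnification)
    slide = SlideImage(levels, downs, pixel_size_um, magnification, slide_id=slide_id)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        Image.fromarray(canvas).save(out_dir / f"{slide_id}.png")
        write_imagescope_xml(ann, out_dir / f"{slide_id}.xml")
    return slide, ann


# --------------------------------------------------------------------------
# Tile corpora
# --------------------------------------------------------------------------

#: Per-class, per-cohort tile counts of a realistic two-cohort training
#: corpus (full scale); the fixture generator defaults to a reduced-scale
#: version with the same proportions.
TABLE_SHAPED_COUNTS: dict[str, dict[GrowthPattern, int]] = {
    "alpha": {
        GrowthPattern.AC: 1533,
        GrowthPattern.MP: 2071,
        GrowthPattern.SO: 2357,
        GrowthPattern.CR: 863,
        GrowthPattern.NT: 3480,
    },
    "beta": {
        GrowthPattern.AC: 2670,
        GrowthPattern.MP: 1165,
        GrowthPattern.SO: 1205,
        GrowthPattern.CR: 2375,
        GrowthPattern.NT: 2223,
    },
}


def scaled_counts(scale: float = 0.01) -> dict[str, dict[GrowthPattern, int]]:
    """The corpus shape at reduced scale (at least one tile per cell)."""
    return {
        cohort: {cls: max(1, round(n * scale)) for cls, n in per.items()}
        for cohort, per in TABLE_SHAPED_COUNTS.items()
    }


def generate_tile_corpus(
    counts: dict[str, dict[GrowthPattern, int]] | None = None,
    tile_px: int = 120,
    seed: int = 0,
    out_dir: str | Path | None = None,
    dry_run: bool = False,
) -> tuple[pd.DataFrame, list[np.ndarray]]:
    """Emit labeled tiles per pseudo-cohort with cohort-specific palettes.

    Returns ``(manifest, tiles)``; the manifest has columns
    ``path, label, source_id, cohort`` and its per-class totals equal the
    requested counts exactly.  In dry-run mode only the manifest is built
    (``tiles`` empty, nothing written) so full-scale counts can be audited
    cheaply.
    """
    counts = counts if counts is not None else scaled_counts()
    rng = np.random.default_rng(seed)
    rows = []
    tiles: list[np.ndarray] = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    for cohort, per_class in counts.items():
        palette = COHORT_PALETTES.get(cohort, COHORT_PALETTES["alpha"])
        for cls, n in per_class.items():
            cls = GrowthPattern(cls) if not isinstance(cls, GrowthPattern) else cls
            for i in range(n):
                source_id = f"{cohort}_{cls.name}_{i:05d}"
                path = f"{source_id}.png"
                if not dry_run:
                    raster = generate_texture(
                        DEFAULT_TEXTURES[cls], tile_px, seed=rng, palette=palette
                    )
                    tiles.append(raster)
                    if out_dir is not None:
                        Image.fromarray(raster).save(out_dir / path)
                        path = str(out_dir / path)
                rows.append((path, cls.name, source_id, cohort))
    manifest = pd.DataFrame(rows, columns=["path", "label", "source_id", "cohort"])
    return manifest, tiles
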