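"""Slide and annotation I/O: pyramids, tile grids, ImageScope XML, masks.

Coordinate conventions: 0-based pixels, x to the right, y down; tiles are
half-open ``[x, x + tile_px) x [y, y + tile_px)`` axis-aligned squares in
level-0 coordinates.  Annotation polygon vertices are level-0 pixel
coordinates; a raster pixel belongs to a polygon when its *center* lies
inside it.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from lxml import etree
from PIL import Image

from .classes import BACKGROUND, GrowthPattern, parse_label

__all__ = [
    "SlideImage",
    "TileGrid",
    "AnnotationRegion",
    "AnnotationSet",
    "GroundTruthMask",
    "open_slide",
    "downsample_rgb",
    "tile_size_for_area",
    "build_tile_grid",
    "parse_imagescope_xml",
    "write_imagescope_xml",
    "rasterize_annotations",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class SlideImage:
    """In-memory RGB slide pyramid with physical metadata.

    ``levels[k]`` is an ``(H, W, 3) uint8`` raster whose integer downsample
    factor relative to level 0 is ``downsamples[k]``.  ``pixel_size_um`` is
    the edge length of one level-0 pixel in microns; ``magnification`` is
    the nominal objective power (20x scans are ~0.5 um/px).
    """

    levels: list[np.ndarray]
    downsamples: list[int]
    pixel_size_um: float
    magnification: float
    slide_id: str = ""

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("slide must have at least one level")
        if self.downsamples[0] != 1:
            raise ValueError("level-0 downsample must be 1")
        if any(b <= a for a, b in zip(self.downsamples, self.downsamples[1:])):
            raise ValueError("downsample factors must be strictly increasing")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def width_px(self) -> int:
        return self.levels[0].shape[1]

    @property
    def height_px(self) -> int:
        return self.levels[0].shape[0]

    def level_for_downsample(self, downsample: float) -> int:
        """Index of the stored level nearest to ``downsample``, preferring
        the nearest *coarser* level when no exact match exists."""
        coarser = [i for i, d in enumerate(self.downsamples) if d >= downsample]
        if coarser:
            return min(coarser, key=lambda i: self.downsamples[i])
        return int(np.argmax(self.downsamples))

    def read_region(self, x: int, y: int, w: int, h: int, level: int = 0) -> np.ndarray:
        """Extract an ``(h, w, 3)`` region; ``x, y`` are level-0 coordinates
        of the top-left corner, ``w, h`` are sizes in level-``level`` pixels."""
        d = self.downsamples[level]
        raster = self.levels[level]
        yl, xl = y // d, x // d
        if xl < 0 or yl < 0 or xl + w > raster.shape[1] or yl + h > raster.shape[0]:
            raise ValueError(
                f"region ({x},{y},{w},{h}) at level {level} exceeds slide bounds"
            )
        return raster[yl : yl + h, xl : xl + w]


@dataclass
class TileGrid:
    """Non-overlapping square tiles covering a slide.

    ``tiles`` holds ``(x, y)`` level-0 top-left corners; ``shape`` is the
    full-grid (rows, cols) before any filtering, used to index tumor maps.
    """

    tile_px: int
    tiles: list[tuple[int, int]]
    slide_width: int
    slide_height: int

    def __post_init__(self) -> None:
        if self.tile_px <= 0:
            raise ValueError("tile_px must be positive")
        for x, y in self.tiles:
            if x < 0 or y < 0 or x + self.tile_px > self.slide_width or y + self.tile_px > self.slide_height:
                raise ValueError(f"tile ({x},{y}) exceeds slide bounds")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.slide_height // self.tile_px, self.slide_width // self.tile_px)

    def __len__(self) -> int:
        return len(self.tiles)


@dataclass
class AnnotationRegion:
    """One closed polygon outline with its tissue class."""

    vertices: np.ndarray  # (n, 2) float, columns (x, y), level-0 pixels
    label: GrowthPattern

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        self.label = GrowthPattern(self.label)


@dataclass
class AnnotationSet:
    """Ordered collection of pathologist annotation regions for one slide."""

    regions: list[AnnotationRegion] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)


@dataclass
class GroundTruthMask:
    """Per-pixel class-code raster rasterized from annotations.

    Values: 0 = unannotated (excluded from evaluation), 1..5 = class codes.
    ``downsample`` relates mask pixels to level-0 pixels.
    """

    labels: np.ndarray  # (H, W) uint8
    downsample: int = 1

    def __post_init__(self) -> None:
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")
        if self.labels.max(initial=0) > 5:
            raise ValueError("mask codes must be in 0..5")


# --------------------------------------------------------------------------
# Slide reading
# --------------------------------------------------------------------------

def downsample_rgb(raster: np.ndarray, factor: int) -> np.ndarray:
    """Integer-factor block-mean (area) downsampling of an RGB raster."""
    if factor == 1:
        return raster
    h, w = raster.shape[:2]
    hc, wc = (h // factor) * factor, (w // factor) * factor
    blocks = raster[:hc, :wc].reshape(h // factor, factor, w // factor, factor, 3)
    return blocks.mean(axis=(1, 3)).round().astype(np.uint8)


def _synthesized_levels(level0: np.ndarray, magnification: float) -> tuple[list[np.ndarray], list[int]]:
    # Provide a coarse level near 5x for tissue masking when only a single
    # resolution is stored.
    levels, downs = [level0], [1]
    factor = max(1, round(magnification / 5.0))
    if factor > 1 and min(level0.shape[:2]) >= factor:
        levels.append(downsample_rgb(level0, factor))
        downs.append(factor)
    return levels, downs


def open_slide(
    path: str | os.PathLike,
    pixel_size_um: float | None = None,
    magnification: float | None = None,
    backend_hint: str | None = None,
) -> SlideImage:
    """Read a slide from PNG/JPEG (single level) or (pyramid) TIFF.

    Plain rasters carry no physical metadata, so ``pixel_size_um`` must be
    supplied (directly or via config) for them; coarser pyramid levels are
    then synthesized by integer block-mean downsampling.  When
    ``magnification`` is omitted it is inferred from the common scanner
    convention 20x ~ 0.5 um/px (``mag = 10 / pixel_size_um``).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"slide file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff", ".svs"} or backend_hint == "tifffile":
        import tifffile

        try:
            with tifffile.TiffFile(path) as tf:
                series = tf.series[0]
                pages = [np.asarray(lvl.asarray()) for lvl in series.levels]
        except Exception as exc:  # corrupt / unreadable
            raise IOError(f"could not read TIFF slide {path}: {exc}") from exc
        w0 = pages[0].shape[1]
        downs = [max(1, round(w0 / p.shape[1])) for p in pages]
        if pixel_size_um is None:
            raise IOError(
                f"{path}: pixel size metadata missing; pass pixel_size_um explicitly"
            )
        mag = magnification if magnification is not None else 10.0 / pixel_size_um
        if len(pages) == 1:
            pages, downs = _synthesized_levels(pages[0], mag)
        return SlideImage(pages, downs, pixel_size_um, mag, slide_id=path.stem)

    try:
        with Image.open(path) as im:
            level0 = np.asarray(im.convert("RGB"))
    except Exception as exc:
        raise IOError(f"could not read slide image {path}: {exc}") from exc
    if pixel_size_um is None:
        raise IOError(f"{path}: pixel size unknown; pass pixel_size_um explicitly")
    mag = magnification if magnification is not None else 10.0 / pixel_size_um
    levels, downs = _synthesized_levels(level0, mag)
    return SlideImage(levels, downs, pixel_size_um, mag, slide_id=path.stem)


# --------------------------------------------------------------------------
# Tiling
# --------------------------------------------------------------------------

def tile_size_for_area(
    pixel_size_um: float,
    reference_tile_px: int = 600,
    reference_pixel_size_um: float = 0.5,
) -> int:
    """Tile edge (px) whose physical area matches the reference tile.

    Scanners differ in pixel size, so a fixed-pixel tile would cover a
    different amount of tissue on each; the edge is rescaled by the pixel
    size ratio so the physical field of view is preserved.
    """
    if pixel_size_um <= 0 or reference_tile_px <= 0 or reference_pixel_size_um <= 0:
        raise ValueError("all tile-size arguments must be positive")
    return round(reference_tile_px * reference_pixel_size_um / pixel_size_um)


def build_tile_grid(slide: SlideImage, tile_px: int) -> TileGrid:
    """Lay a non-overlapping grid of ``tile_px`` squares from the origin.

    Partial tiles that would extend past the slide boundary are omitted
    (classifier input size is fixed).
    """
    if tile_px <= 0:
        raise ValueError("tile_px must be positive")
    if tile_px > min(slide.width_px, slide.height_px):
        raise ValueError(
            f"tile_px={tile_px} exceeds slide dimensions "
            f"{slide.width_px}x{slide.height_px}"
        )
    tiles = [
        (x, y)
        for y in range(0, slide.height_px - tile_px + 1, tile_px)
        for x in range(0, slide.width_px - tile_px + 1, tile_px)
    ]
    return TileGrid(tile_px, tiles, slide.width_px, slide.height_px)


# --------------------------------------------------------------------------
# ImageScope annotation XML
# --------------------------------------------------------------------------

def parse_imagescope_xml(
    path: str | os.PathLike | io.IOBase,
    label_attr: str = "Text",
    label_map=None,
) -> AnnotationSet:
    """Parse Aperio ImageScope annotation XML into an :class:`AnnotationSet`.

    The dialect is ``Annotations/Annotation/Regions/Region/Vertices/Vertex``
    with the class label carried in a ``Region`` attribute (default
    ``Text``).  Vertex ``X``/``Y`` are taken as level-0 pixel coordinates.
    Unknown labels raise ``ValueError`` naming the label.
    """
    try:
        tree = etree.parse(path if hasattr(path, "read") else str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed ImageScope XML: {exc}") from exc
    regions: list[AnnotationRegion] = []
    for region in tree.iter("Region"):
        raw = region.get(label_attr)
        if raw is None:
            raise ValueError(
                f"Region element missing label attribute {label_attr!r}"
            )
        label = parse_label(raw, label_map)
        verts = [
            (float(v.get("X")), float(v.get("Y")))
            for v in region.iter("Vertex")
        ]
        regions.append(AnnotationRegion(np.array(verts), label))
    return AnnotationSet(regions)


def write_imagescope_xml(
    ann: AnnotationSet,
    path: str | os.PathLike,
    label_attr: str = "Text",
) -> None:
    """Serialize annotations back to the ImageScope XML dialect."""
    root = etree.Element("Annotations")
    annotation = etree.SubElement(root, "Annotation", Id="1")
    regions_el = etree.SubElement(annotation, "Regions")
    for i, region in enumerate(ann.regions, start=1):
        attrs = {"Id": str(i), label_attr: region.label.long_name}
        region_el = etree.SubElement(regions_el, "Region", **attrs)
        verts_el = etree.SubElement(region_el, "Vertices")
        for x, y in region.vertices:
            etree.SubElement(verts_el, "Vertex", X=repr(float(x)), Y=repr(float(y)))
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# --------------------------------------------------------------------------
# Rasterization
# --------------------------------------------------------------------------

def rasterize_annotations(
    ann: AnnotationSet,
    slide: SlideImage | tuple[int, int],
    downsample: int = 1,
    overlap: str = "error",
) -> GroundTruthMask:
    """Fill annotation polygons with their class codes into a label raster.

    A pixel gets a polygon's code when its center lies strictly inside the
    polygon.  Overlapping polygons of *different* classes raise by default;
    ``overlap="last-wins"`` lets later regions take precedence (annotation
    order is preserved from the XML).
    """
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    if overlap not in {"error", "last-wins"}:
        raise ValueError("overlap must be 'error' or 'last-wins'")
    if isinstance(slide, SlideImage):
        w, h = slide.width_px, slide.height_px
    else:
        w, h = slide
    mh, mw = int(np.ceil(h / downsample)), int(np.ceil(w / downsample))
    labels = np.zeros((mh, mw), dtype=np.uint8)
    for region in ann.regions:
        poly = shapely.Polygon(region.vertices)
        minx, miny, maxx, maxy = poly.bounds
        j0 = max(0, int((minx / downsample) - 1))
        j1 = min(mw, int(np.ceil(maxx / downsample)) + 1)
        i0 = max(0, int((miny / downsample) - 1))
        i1 = min(mh, int(np.ceil(maxy / downsample)) + 1)
        if j1 <= j0 or i1 <= i0:
            continue
        jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
        cx = (jj + 0.5) * downsample
        cy = (ii + 0.5) * downsample
        inside = shapely.contains_xy(poly, cx.ravel(), cy.ravel()).reshape(ii.shape)
        sub = labels[i0:i1, j0:j1]
        clash = inside & (sub != BACKGROUND) & (sub != int(region.label))
        if overlap == "error" and clash.any():
            raise ValueError(
                "overlapping annotation polygons of different classes; "
                "pass overlap='last-wins' to let later regions take precedence"
            )
        sub[inside] = int(region.label)
    return GroundTruthMask(labels, downsample)
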