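"""Tile geometry, annotation XML round-trips, and polygon rasterization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

from growthmap.classes import GrowthPattern
from growthmap.slide_io import (
    AnnotationRegion,
    AnnotationSet,
    GroundTruthMask,
    build_tile_grid,
    open_slide,
    parse_imagescope_xml,
    rasterize_annotations,
    tile_size_for_area,
    write_imagescope_xml,
)

from conftest import make_slide


# --------------------------------------------------------------------------
# open_slide
# --------------------------------------------------------------------------

def test_open_png_synthesizes_coarse_level(tmp_path):
    """A 512x512 PNG at 0.5 um/px (20x) gains a synthesized 4x-downsample
    level so tissue masking can run near 5x."""
    img = np.random.default_rng(0).integers(0, 255, (512, 512, 3), dtype=np.uint8)
    path = tmp_path / "slide.png"
    Image.fromarray(img).save(path)
    slide = open_slide(path, pixel_size_um=0.5)
    assert slide.downsamples == [1, 4]
    assert slide.magnification == pytest.approx(20.0)
    assert slide.levels[1].shape == (128, 128, 3)


def test_open_pyramid_tiff_preserves_levels(tmp_path):
    import tifffile

    rng = np.random.default_rng(1)
    base = rng.integers(0, 255, (256, 256, 3), dtype=np.uint8)
    path = tmp_path / "pyramid.tif"
    with tifffile.TiffWriter(path) as tw:
        tw.write(base, subifds=2)
        tw.write(base[::2, ::2], subfiletype=1)
        tw.write(base[::4, ::4], subfiletype=1)
    slide = open_slide(path, pixel_size_um=0.5)
    assert slide.downsamples == [1, 2, 4]


def test_open_corrupt_file_raises(tmp_path):
    path = tmp_path / "bad.png"
    path.write_bytes(b"this is not an image")
    with pytest.raises(IOError):
        open_slide(path, pixel_size_um=0.5)


def test_missing_pixel_size_is_an_error(tmp_path):
    path = tmp_path / "s.png"
    Image.fromarray(np.zeros((32, 32, 3), dtype=np.uint8)).save(path)
    with pytest.raises(IOError, match="pixel size"):
        open_slide(path)


# --------------------------------------------------------------------------
# tile_size_for_area
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pixel_size,expected",
    [(0.5, 600), (0.25, 1200), (1.0, 300), (0.4, 750)],
)
def test_tile_size_matches_physical_area(pixel_size, expected):
    """The tile edge scales inversely with pixel size so the physical field
    of view equals the 600 px / 0.5 um reference."""
    assert tile_size_for_area(pixel_size, 600, 0.5) == expected


def test_tile_size_rejects_nonpositive():
    with pytest.raises(ValueError):
        tile_size_for_area(0.0, 600, 0.5)
    with pytest.raises(ValueError):
        tile_size_for_area(0.5, -600, 0.5)


# --------------------------------------------------------------------------
# build_tile_grid
# --------------------------------------------------------------------------

def test_grid_enumeration_1800x1200():
    slide = make_slide(1800, 1200)
    grid = build_tile_grid(slide, 600)
    assert sorted(grid.tiles) == sorted(
        [(x, y) for x in (0, 600, 1200) for y in (0, 600)]
    )


def test_grid_single_tile_and_too_small():
    assert build_tile_grid(make_slide(600, 600), 600).tiles == [(0, 0)]
    with pytest.raises(ValueError):
        build_tile_grid(make_slide(599, 600), 600)


@settings(deadline=None, max_examples=50)
@given(
    w=st.integers(50, 400),
    h=st.integers(50, 400),
    tile=st.integers(7, 50),
)
def test_grid_tiles_disjoint_and_within_slide(w, h, tile):
    """Tiles never overlap and their total area never exceeds the slide's
    (area bookkeeping over the half-open footprints)."""
    grid = build_tile_grid(make_slide(w, h), tile)
    assert len(set(grid.tiles)) == len(grid.tiles)
    assert len(grid) == (w // tile) * (h // tile)
    cover = np.zeros((h, w), dtype=np.int32)
    for x, y in grid.tiles:
        cover[y : y + tile, x : x + tile] += 1
    assert cover.max() == 1
    assert cover.sum() == len(grid) * tile * tile <= w * h


# --------------------------------------------------------------------------
# ImageScope XML
# --------------------------------------------------------------------------

TRIANGLE_XML = """<?xml version="1.0"?>
<Annotations>
 <Annotation Id="1">
  <Regions>
   <Region Id="1" Text="solid">
    <Vertices>
     <Vertex X="10" Y="10"/><Vertex X="50" Y="10"/><Vertex X="30" Y="40"/>
    </Vertices>
   </Region>
  </Regions>
 </Annotation>
</Annotations>
"""


def test_parse_single_region(tmp_path):
    path = tmp_path / "ann.xml"
    path.write_text(TRIANGLE_XML)
    ann = parse_imagescope_xml(path)
    assert len(ann) == 1
    assert ann.regions[0].label == GrowthPattern.SO
    assert ann.regions[0].vertices.shape == (3, 2)


def test_parse_unknown_label_names_offender(tmp_path):
    path = tmp_path / "ann.xml"
    path.write_text(TRIANGLE_XML.replace("solid", "lepidic"))
    with pytest.raises(ValueError, match="lepidic"):
        parse_imagescope_xml(path)


def test_parse_malformed_xml(tmp_path):
    path = tmp_path / "broken.xml"
    path.write_text("<Annotations><Region>")
    with pytest.raises(ValueError, match="malformed"):
        parse_imagescope_xml(path)


def test_parse_preserves_region_order(tmp_path):
    ann = AnnotationSet(
        [
            AnnotationRegion([(0, 0), (9, 0), (9, 9)], GrowthPattern.AC),
            AnnotationRegion([(20, 20), (29, 20), (29, 29)], GrowthPattern.NT),
        ]
    )
    path = tmp_path / "two.xml"
    write_imagescope_xml(ann, path)
    parsed = parse_imagescope_xml(path)
    assert [r.label for r in parsed] == [GrowthPattern.AC, GrowthPattern.NT]


def test_xml_roundtrip_is_stable(tmp_path, rng):
    """parse -> serialize -> parse preserves labels and coordinates."""
    regions = [
        AnnotationRegion(rng.uniform(0, 500, size=(5, 2)), cls)
        for cls in GrowthPattern
    ]
    p1, p2 = tmp_path / "a.xml", tmp_path / "b.xml"
    write_imagescope_xml(AnnotationSet(regions), p1)
    ann1 = parse_imagescope_xml(p1)
    write_imagescope_xml(ann1, p2)
    ann2 = parse_imagescope_xml(p2)
    for r1, r2 in zip(ann1, ann2):
        assert r1.label == r2.label
        np.testing.assert_array_equal(r1.vertices, r2.vertices)


# --------------------------------------------------------------------------
# rasterize_annotations
# --------------------------------------------------------------------------

def brute_force_inside(poly, px, py):
    """Even-odd (crossing number) point-in-polygon, written independently."""
    crossings = 0
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_at = x1 + (py - y1) / (y2 - y1) * (x2 - x1)
            if px < x_at:
                crossings += 1
    return crossings % 2 == 1


def test_square_rasterizes_to_exact_area(square_annotation):
    mask = rasterize_annotations(square_annotation, (20, 20), downsample=1)
    assert (mask.labels == int(GrowthPattern.AC)).sum() == 100
    assert (mask.labels != 0).sum() == 100


def test_empty_annotation_set_gives_zero_mask():
    mask = rasterize_annotations(AnnotationSet([]), (16, 16), downsample=1)
    assert mask.labels.sum() == 0


def test_two_disjoint_squares_codes_and_areas():
    ann = AnnotationSet(
        [
            AnnotationRegion([(2, 2), (10, 2), (10, 10), (2, 10)], GrowthPattern.AC),
            AnnotationRegion([(20, 20), (30, 20), (30, 30), (20, 30)], GrowthPattern.NT),
        ]
    )
    mask = rasterize_annotations(ann, (40, 40), downsample=1)
    assert (mask.labels == 1).sum() == 64
    assert (mask.labels == 5).sum() == 100


def test_overlapping_classes_error_and_last_wins():
    overlapping = AnnotationSet(
        [
            AnnotationRegion([(0, 0), (10, 0), (10, 10), (0, 10)], GrowthPattern.AC),
            AnnotationRegion([(5, 5), (15, 5), (15, 15), (5, 15)], GrowthPattern.SO),
        ]
    )
    with pytest.raises(ValueError, match="overlap"):
        rasterize_annotations(overlapping, (20, 20))
    mask = rasterize_annotations(overlapping, (20, 20), overlap="last-wins")
    assert mask.labels[7, 7] == int(GrowthPattern.SO)


@settings(deadline=None, max_examples=25)
@given(seed=st.integers(0, 10_000))
def test_rasterization_matches_brute_force_oracle(seed):
    """On small slides, every pixel's code equals the independent
    crossing-number test applied to its center."""
    rng = np.random.default_rng(seed)
    polys = []
    for cls in (GrowthPattern.AC, GrowthPattern.NT):
        cx, cy = rng.uniform(10, 50, size=2)
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=5))
        radius = rng.uniform(4, 9)
        verts = np.c_[cx + radius * np.cos(angles), cy + radius * np.sin(angles)]
        polys.append(AnnotationRegion(verts, cls))
    try:
        mask = rasterize_annotations(AnnotationSet(polys), (64, 64), downsample=1)
    except ValueError:
        return  # overlapping random polygons: rejection is the contract
    for i in range(64):
        for j in range(64):
            expected = 0
            for region in polys:
                if brute_force_inside(region.vertices, j + 0.5, i + 0.5):
                    expected = int(region.label)
            assert mask.labels[i, j] == expected


def test_rasterize_at_downsample():
    ann = AnnotationSet(
        [AnnotationRegion([(0, 0), (20, 0), (20, 20), (0, 20)], GrowthPattern.MP)]
    )
    mask = rasterize_annotations(ann, (40, 40), downsample=2)
    assert mask.labels.shape == (20, 20)
    assert (mask.labels == 2).sum() == 100  # centers (2k+1) < 20 for k<10


def test_mask_code_range_validated():
    with pytest.raises(ValueError):
        GroundTruthMask(np.full((4, 4), 9, dtype=np.uint8))
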