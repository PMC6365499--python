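# growthmap

Whole-slide-image (WSI) analysis pipeline that maps the architectural
growth patterns of lung adenocarcinoma — **acinar (AC)**, **micropapillary
(MP)**, **solid (SO)**, **cribriform (CR)** — plus **non-tumor (NT)**
tissue, and scores the resulting tumor maps against pathologist
annotations.

Growth-pattern composition carries prognostic weight in lung
adenocarcinoma, but quantifying it by eye across gigapixel slides is slow
and irreproducible. `growthmap` implements the full computational path
from scanned slide to quantified, evaluated tumor map, with a pluggable
tile classifier so that any model satisfying a simple probability
contract (a CNN, or the built-in deterministic reference classifier) can
drive it.

## Pipeline

1. **Tissue masking** — threshold a ~5x gray rendering at *t* = 230,
   fill enclosed holes, morphologically close; drop tiles with < 20%
   tissue.
2. **Tiling** — non-overlapping square tiles (600 px at the 0.5 µm/px
   reference scale; the edge rescales with pixel size so the physical
   field of view matches across scanners).
3. **Color handling** — Reinhard color transfer in the decorrelated
   log-chromatic lαβ space; transfer targets are derived by k-means over
   tile corpora (4 patterns from two staining cohorts). Training tiles
   expand by the color × orientation product, (1 + 4) × 8 = 40 variants
   per tile.
4. **Contextual soft voting** — each tile is classified together with
   eight overlapping glimpses shifted by ⅓ of the tile edge; the label is

   ŷ = argmax_i Σ_{j=1}^{N} a_j · p_ij,   uniform a_j, N = 9,

   where p_ij is glimpse *j*'s probability for class *i*.
5. **Tumor maps & evaluation** — per-tile label grids, class percentages
   (optionally in 5% increments), 5×5 pixel-count confusion matrices
   (rows = ground truth, columns = predicted) aggregated slide → set →
   study, per-class F1 and accuracy, tumor-vs-non-tumor merging, and
   rank-sum / signed-rank comparisons.

Everything is exercisable offline: the `synthetic` module generates
seeded annotated slides with five feature-separable texture families and
two staining palettes, and the `MockClassifier` maps interpretable
morphological features (foreground fraction, component size, lumina per
component) to classes deterministically.

## Worked example

```python
from growthmap.classifier import MockClassifier
from growthmap.contextual_voting import classify_slide
from growthmap.evaluation import confusion_from_overlay, metrics
from growthmap.slide_io import build_tile_grid, rasterize_annotations
from growthmap.synthetic import default_slide_layout, generate_slide
from growthmap.tissue_masking import compute_tissue_mask, filter_tiles
from growthmap.tumor_map import class_percentages

layout = default_slide_layout(tile_px=120, seed=0)
slide, annotations = generate_slide(layout, seed=0, palette="beta")

mask = compute_tissue_mask(slide, threshold=230)
grid = filter_tiles(build_tile_grid(slide, 120), mask, min_tissue_fraction=0.20)
print(f"{len(grid)} tissue tiles retained")

tumor_map = classify_slide(slide, grid, MockClassifier())
pct = class_percentages(tumor_map, round_to_5=True)
print({c.name: v for c, v in pct["tumor"].items()})

gt = rasterize_annotations(annotations, slide, downsample=4)
report = metrics(confusion_from_overlay(tumor_map, gt))
print(f"accuracy {report.accuracy:.3f}")
print({c.name: round(f, 3) for c, f in report.f1.items()})
```

Output:

```
45 tissue tiles retained
{'AC': 25.0, 'MP': 25.0, 'SO': 25.0, 'CR': 25.0}
accuracy 1.000
{'AC': 1.0, 'MP': 1.0, 'SO': 1.0, 'CR': 1.0, 'NT': 1.0}
```

The synthetic slide holds one equally sized region per class, so the
tumor-relative percentages split 25/25/25/25 across the four growth
patterns; the pixel-level confusion against the rasterized annotation
polygons is perfect on this slide.

The same flow is available from the shell:

```bash
growthmap synth slide --seed 0 --tile-px 120 --out slides/
growthmap report --slides slides/ --annotations slides/ --pixel-size 2.5 --out report/
```

## Layout

| Module | Role |
| --- | --- |
| `growthmap.slide_io` | slide pyramids, tile grids, ImageScope XML, polygon rasterization |
| `growthmap.tissue_masking` | low-magnification tissue mask, tile filtering |
| `growthmap.stain_color` | lαβ conversion, Reinhard transfer, k-means color patterns |
| `growthmap.augmentation` | color × orientation training-set expansion |
| `growthmap.classifier` | classifier contract, rule-based reference model, compact trainable convolutional backend |
| `growthmap.contextual_voting` | glimpse geometry, soft voting, whole-slide classification |
| `growthmap.tumor_map` | label grids, percentages, overlay rendering |
| `growthmap.evaluation` | confusion matrices, F1/ACC, category merging, rank tests |
| `growthmap.synthetic` | seeded synthetic slides, tiles, annotations |
| `growthmap.cli` / `growthmap.config` | `growthmap` command-line interface and layered YAML config |

See `docs/methods.md` for the modelling choices, defaults, and known
limitations.
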