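# Methods

## Problem setting

Lung adenocarcinoma grows in distinct architectural patterns — acinar
(gland-forming), micropapillary (small tufts without fibrovascular
cores), solid (sheets), cribriform (sieve-like perforated nests) — whose
relative proportions inform prognosis. `growthmap` turns a scanned H&E
slide into a per-tile map over these four patterns plus non-tumor tissue,
quantifies the composition, and scores maps against pathologist polygon
annotations. The classifier itself is pluggable; the package's substance
is everything around it: geometry, color handling, contextual voting,
quantification and evaluation.

## Coordinates and tiling

All coordinates are 0-based level-0 pixels, x right, y down; tiles are
half-open `[x, x+T) × [y, y+T)` squares placed at multiples of the tile
edge from the slide origin, with partial edge tiles dropped (the
classifier input size is fixed). The reference tile is **600 px at
0.5 µm/px** (a 20x scan); for other pixel sizes the edge is
`round(600 · 0.5 / pixel_size)` so the physical field of view is
preserved across scanners. Annotation polygons are interpreted in level-0
pixels, and a raster pixel belongs to a polygon when its **center** lies
inside it; overlapping polygons of different classes are an error by
default (silent precedence would hide annotation bugs) with an explicit
`last-wins` override. Nominal magnification, when a plain raster carries
none, is inferred from the scanner convention `mag = 10 / pixel_size_µm`.

## Tissue masking

Foreground is `gray < 230` (Rec. 601 luma) on the pyramid level nearest
5x, preferring the nearest coarser level when no exact one exists.
Enclosed background pockets are then filled (background components not
connected to the raster border) and the mask is closed with a square
5×5 structuring element. Neither the closing kernel nor the hole-filling
connectivity has a canonical value, so both are configurable; the
defaults were chosen once as the smallest cleanup that bridges
intra-tissue gaps at 5x. A tile is retained when its foreground fraction
is **≥ 0.20** — the boundary is inclusive: exactly 20% survives, strictly
below is deleted.

## Color model

"Lab" here is Reinhard's decorrelated log-chromatic **lαβ** space: RGB
(scaled to [0,1]) → LMS cone responses → log₁₀ → fixed decorrelating
transform (achromatic l, yellow-blue α, red-green β). LMS values are
clamped at 1e-6 before the log so black stays finite. The inverse uses
the **exact matrix inverse** of the forward cone matrix rather than the
commonly printed 4-decimal rounding of it; the rounded inverse costs up
to 2 intensity levels on saturated pixels and would break the
within-one-level round-trip guarantee. A side effect of keeping the
published forward matrix (whose rows do not sum exactly to 1) is that
achromatic pixels carry a residual chroma of ~1e-3, which is below
visual relevance and is documented in the tests.

Transfer matches per-channel mean and standard deviation in lαβ:
`out = (in − µ_src) · σ_tgt / max(σ_src, 1e-6) + µ_tgt`; the ε guard
collapses constant channels to the target mean. Transfer targets
("color patterns") are derived by k-means (scikit-learn, k-means++
seeding, 300-iteration cap, ≤10⁵ subsampled pixels per corpus) run
**separately per staining cohort** with the total k split evenly — two
cohorts and k = 4 give 2 clusters each, matching a two-laboratory
training corpus. Clusters are ordered by luminance mean for
deterministic pattern identities. The inference-time normalization
target defaults to the pooled-training-corpus statistics and is
config-selectable, since no single canonical choice exists.

## Augmentation

Each labeled tile expands into `(1 + n_patterns) × 8` variants: the
original plus one Reinhard transfer per pattern, each in the 8 square
symmetries (4 rotations of the original, then 4 rotations of the
transpose). With 4 patterns that is 40 variants, taking a 19,942-tile
two-cohort corpus to 797,680 training rows; the factor is identical for
every row, so class proportions are preserved exactly. A dry-run mode
counts variants without writing files. Downsizing to the classifier
input (256 px, area resampling) happens at classification time, not at
augmentation time, so augmented archives stay resolution-faithful.

## Classifier contract and backends

A classifier maps a batch of RGB tiles to one probability vector per
tile over (AC, MP, SO, CR, NT), entries ≥ 0 summing to 1 ± 1e-6; the
pipeline enforces the contract on every batch. Input standardization is
zero-mean/unit-variance per channel over the batch (ε-guarded for
constant batches).

Two backends ship:

* **MockClassifier** — deterministic decision rules over interpretable
  morphology of the dark-foreground mask (luma < 180): near-zero
  foreground → NT; mean lumina per connected component ≥ 1.5 → CR;
  ≥ 0.35 → AC; otherwise mean component area ≥ 250 px² → SO, else MP.
  The winner gets probability 0.9 (configurable, so voting experiments
  can control disagreement), the rest split the remainder. These
  thresholds are keyed to the synthetic texture definitions below and
  sit well clear of the measured class feature distributions, including
  glimpses clipped at region borders.
* **Trainable backend** — a compact convolutional model: a bank of 16
  seed-derived fixed random 7×7 filters with ReLU and pooled activation
  statistics feeding a trained MLP readout (scikit-learn), with stored
  feature standardization moments. Fully seeded: identical data, config
  and seed give identical predictions. It reaches ≥ 0.9 held-out
  accuracy on the synthetic textures. Full-scale deep-CNN training is
  deliberately out of scope; the pipeline treats any contract-satisfying
  model identically.

## Contextual soft voting

For each retained tile, eight glimpses are taken at offsets
`(dx, dy) ∈ {−s, 0, +s}² \ {(0,0)}` with `s = round(T/3)`; the nine
probability vectors combine as `ŷ = argmax_i Σ_j a_j p_ij` with uniform
weights. The vote is permutation invariant; ties break deterministically
toward the lowest class index (AC < MP < SO < CR < NT). Glimpses
extending beyond the slide are **dropped** (N shrinks; the central tile
is always kept) rather than padded or clamped — padding would fabricate
tissue. A configured neighborhood of 1 degenerates to central-tile-only
classification, which is the baseline the voting is compared against.
Each glimpse is normalized and classified independently. Whether to
Reinhard-normalize at inference is a parameter: the rule-based reference
classifier is keyed to the raw synthetic texture intensities (it stands
in for a model trained on those colors), so the synthetic end-to-end
runs classify un-normalized glimpses, while the normalization path has
its own identity/idempotence guarantees.

## Quantification and evaluation

Tumor maps are per-tile label grids; composition is reported as
percentages of all tissue tiles and of tumor tiles only (tiles are
equal-area, so counts are area fractions at map resolution), optionally
rounded to 5% increments with largest-remainder correction so rounded
values still sum to 100 — the granularity at which pathologists report
pattern composition.

Scoring superimposes the map on the rasterized annotation mask at the
mask's resolution: every annotated pixel is tallied against the class of
the tile covering its center into a 5×5 matrix (rows = truth, columns =
predicted). Annotated pixels over unclassified (background) tiles are
tallied in a separate per-class vector rather than folded into NT, which
would bias the non-tumor row. Slide matrices sum entrywise into set- and
study-level matrices; `F1_i = 2·TP_i / (2·TP_i + FP_i + FN_i)` (0 when
the denominator is 0) and `ACC = trace/total` follow from any matrix.
Merging collapses the four growth patterns into one tumor category, so
within-tumor confusion becomes correct by construction.

The rank tests (rank-sum for independent samples, signed-rank for paired
ones) use exact enumeration when the relevant sample size is ≤ 12 and
tie-free, otherwise the normal approximation with tie correction
(delegated to SciPy; independent enumeration oracles live in the test
suite). Zero paired differences are dropped; an all-zero comparison is
vacuous and returns p = 1 with a warning. No multiple-comparison
correction is applied; p-values are reported raw.

## Synthetic fixtures

The generator emulates the *statistical* structure of annotated WSIs,
not their histology: rectangular class regions on a bright optical
background (~luma 245), matching ImageScope-dialect XML, and tile
manifests shaped like a two-cohort training corpus (full-scale totals
10,304 + 9,638 = 19,942). Texture families are feature-separable by
construction: SO = large solid discs; AC = annuli (one lumen each);
CR = blobs with 3–5 lumina; MP = tufts of tiny dots over a pale stromal
under-wash (the wash keeps MP tiles above the 20% tissue cutoff without
adding dark foreground); NT = sparse pale elements whose luma (~215–220)
sits between the mock's dark-foreground cutoff (180) and the tissue-mask
threshold (230). Two palettes ("alpha" pink-purple, "beta" darker
blue-purple) emulate inter-laboratory staining variance. Element
placement is rejection-sampled non-overlapping; all generation is
bit-reproducible from a seed.

The default slide layout places one 3×3-tile region per class on a
tile-aligned grid with one-tile gaps, so glimpses from one region never
reach another and region tiles are texture-pure; desk-scale runs use
120 px tiles (the geometry is scale-free, and this keeps a ten-slide
end-to-end evaluation around ten seconds). Measured at defaults, the
mock classifies generator tiles at 100% (well above the ≥ 95%
separability contract) and ten-slide study-level pixel accuracy is
~0.998 with every per-class F1 ≥ 0.99.

**What passing synthetic tests does and does not show.** They verify the
pipeline's geometry, color arithmetic, voting, bookkeeping and scoring
end to end — not that any classifier recognizes real H&E morphology.
Real slides add nuclear texture, stain physics, pen marks, blur and
scanner artifacts that the generator deliberately omits; published
headline performance on real cohorts requires the original slides and
trained CNN weights and is not claimed or reproduced here.

## Numerical and degenerate-input choices

* LMS log clamp 1e-6; Reinhard σ guard 1e-6; probability tolerance 1e-6.
* Constant tiles: transfer collapses them to the target mean; batch
  standardization maps constant batches to zero.
* Empty inputs raise (empty corpus, empty batch is an empty result,
  empty matrix list, empty samples); all-background maps warn and return
  empty summaries.
* Tile-retention and glimpse-shift rounding use `round()`; the grid
  drops partial edge tiles; fractions are computed over mask pixels
  whose centers fall in the tile footprint.
* Seeds are mandatory in the config for stochastic paths; the CLI
  refuses to run them without one.

## Known limitations

* No stain-deconvolution normalization (Macenko/Vahadane-style), no
  blur/artifact QC, no pen-mark removal, no adaptive thresholding.
* SVS reading depends on `tifffile`'s ability to parse the container;
  MRXS is unsupported without an external WSI backend.
* The rule-based classifier is meaningful only on the synthetic texture
  families; on real tissue it is a placeholder for a trained model.
* Glimpse border handling (drop vs clamp) and the inference
  normalization target are genuinely open choices; both defaults are
  documented above and config-exposed.
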