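"""Scoring tumor maps against pathologist ground truth.

Slide-level 5x5 confusion matrices (rows = ground truth, columns =
predicted) are built by superimposing the tumor map on the rasterized
annotation mask and counting pixels.  Set- and study-level matrices are
entrywise sums of slide-level ones; accuracy and per-class F1 follow
directly from a matrix.  Nonparametric two-sample comparisons (rank-sum
for independent samples, signed-rank for paired ones) support
slide-accuracy contrasts between models or cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classes import ALL_CLASSES, BACKGROUND, TUMOR_CLASSES, GrowthPattern
from .slide_io import GroundTruthMask
from .tumor_map import TumorMap

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_from_overlay",
    "aggregate",
    "metrics",
    "merge_tumor_vs_nontumor",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
]

N = len(ALL_CLASSES)

#: Sample-size cap below which the rank tests use exact enumeration.
EXACT_TEST_MAX_N = 12


@dataclass
class ConfusionMatrix:
    """Pixel-count confusion matrix over the five tissue classes.

    ``unclassified`` tallies annotated pixels that fell over background
    (unclassified) tiles, per ground-truth class; they are reported
    separately rather than folded into any predicted class.
    """

    counts: np.ndarray  # (5, 5) int64, rows = truth, cols = predicted
    level: str = "slide"
    unclassified: np.ndarray = field(default_factory=lambda: np.zeros(N, dtype=np.int64))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.unclassified = np.asarray(self.unclassified, dtype=np.int64)
        if self.counts.shape != (N, N):
            raise ValueError("confusion matrix must be 5x5")
        if (self.counts < 0).any() or (self.unclassified < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Per-class F1 and overall accuracy derived from one matrix."""

    f1: dict[GrowthPattern, float]
    accuracy: float


def confusion_from_overlay(tmap: TumorMap, gt: GroundTruthMask, level: str = "slide") -> ConfusionMatrix:
    """Tally annotated pixels against the covering tile's predicted class.

    Counting happens at the ground-truth raster's resolution: each mask
    pixel with a nonzero code is assigned the predicted class of the tile
    covering its center.  Pixels over background tiles are tallied in the
    separate ``unclassified`` vector.
    """
    rows, cols = tmap.labels.shape
    gh, gw = gt.labels.shape
    if gw * gt.downsample < cols * tmap.tile_px or gh * gt.downsample < rows * tmap.tile_px:
        raise ValueError("ground-truth mask and tumor map frames do not match")
    ii, jj = np.nonzero(gt.labels)
    truth = gt.labels[ii, jj].astype(np.int64)
    # tile covering the gt pixel's center, in level-0 coordinates
    ty = ((ii + 0.5) * gt.downsample / tmap.tile_px).astype(np.int64)
    tx = ((jj + 0.5) * gt.downsample / tmap.tile_px).astype(np.int64)
    in_grid = (ty < rows) & (tx < cols)
    pred = np.zeros(len(ii), dtype=np.int64)
    pred[in_grid] = tmap.labels[ty[in_grid], tx[in_grid]]
    counts = np.zeros((N, N), dtype=np.int64)
    unclassified = np.zeros(N, dtype=np.int64)
    classified = pred != BACKGROUND
    np.add.at(counts, (truth[classified] - 1, pred[classified] - 1), 1)
    np.add.at(unclassified, truth[~classified] - 1, 1)
    return ConfusionMatrix(counts, level=level, unclassified=unclassified)


def aggregate(matrices: list[ConfusionMatrix], level: str = "study") -> ConfusionMatrix:
    """Entrywise sum of confusion matrices (slide → set → study)."""
    if not matrices:
        raise ValueError("cannot aggregate an empty list of matrices")
    counts = np.sum([m.counts for m in matrices], axis=0)
    unclassified = np.sum([m.unclassified for m in matrices], axis=0)
    return ConfusionMatrix(counts, level=level, unclassified=unclassified)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy and per-class F1 from a confusion matrix.

    ``F1_i = 2 TP_i / (2 TP_i + FP_i + FN_i)`` with TP on the diagonal; a
    class with an empty denominator gets F1 = 0.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2 * tp / denom, 0.0)
    acc = float(tp.sum() / counts.sum())
    return MetricsReport({c: float(f1[int(c) - 1] )for c in ALL_CLASSES}, acc)


def merge_tumor_vs_nontumor(cm: ConfusionMatrix) -> tuple[np.ndarray, dict]:
    """Collapse the four growth patterns into one tumor category.

    Returns the 2x2 matrix (rows/cols: tumor, non-tumor) plus binary F1
    for each category and overall accuracy.  Within-tumor confusion
    becomes correct by construction.
    """
    t = [int(c) - 1 for c in TUMOR_CLASSES]
    n = int(GrowthPattern.NT) - 1
    c = cm.counts
    m2 = np.array(
        [
            [c[np.ix_(t, t)].sum(), c[t, n].sum()],
            [c[n, t].sum(), c[n, n]],
        ],
        dtype=np.int64,
    )
    tp_t, fn_t, fp_t = m2[0, 0], m2[0, 1], m2[1, 0]
    tp_n, fn_n, fp_n = m2[1, 1], m2[1, 0], m2[0, 1]
    f1_t = 2 * tp_t / (2 * tp_t + fp_t + fn_t) if (2 * tp_t + fp_t + fn_t) else 0.0
    f1_n = 2 * tp_n / (2 * tp_n + fp_n + fn_n) if (2 * tp_n + fp_n + fn_n) else 0.0
    acc = (m2[0, 0] + m2[1, 1]) / m2.sum() if m2.sum() else 0.0
    return m2, {"f1_tumor": float(f1_t), "f1_nontumor": float(f1_n), "accuracy": float(acc)}


def wilcoxon_rank_sum(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided rank-sum (Mann-Whitney) test for independent samples.

    Exact p by enumeration when the combined sample size is at most
    ``EXACT_TEST_MAX_N`` and there are no ties; otherwise the normal
    approximation with tie correction.  Returns (U statistic, p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    exact = no_ties and (len(a) + len(b) <= EXACT_TEST_MAX_N)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def wilcoxon_signed_rank(paired_a, paired_b) -> tuple[float, float]:
    """Two-sided signed-rank test on paired differences.

    Zero differences are dropped before ranking; if every difference is
    zero the test is vacuous and (0, 1) is returned with a warning.  Exact
    p for at most ``EXACT_TEST_MAX_N`` nonzero pairs without tied absolute
    differences; normal approximation otherwise.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) == 0:
        raise ValueError("samples must be non-empty")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero; signed-rank test is vacuous")
        return 0.0, 1.0
    absd = np.abs(d)
    no_ties = len(np.unique(absd)) == len(absd)
    exact = no_ties and len(d) <= EXACT_TEST_MAX_N
    res = stats.wilcoxon(
        d, alternative="two-sided", method="exact" if exact else "approx"
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))
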