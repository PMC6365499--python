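"""Confusion matrices, metrics, category merging, and rank tests."""

import itertools

import numpy as np
import pytest

from growthmap.classes import ALL_CLASSES, GrowthPattern
from growthmap.evaluation import (
    ConfusionMatrix,
    aggregate,
    confusion_from_overlay,
    merge_tumor_vs_nontumor,
    metrics,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from growthmap.slide_io import GroundTruthMask
from growthmap.tumor_map import TumorMap


def make_pair(map_labels, gt_labels, tile_px=10, gt_downsample=1):
    tmap = TumorMap(labels=np.asarray(map_labels, dtype=np.uint8), tile_px=tile_px)
    gt = GroundTruthMask(np.asarray(gt_labels, dtype=np.uint8), downsample=gt_downsample)
    return tmap, gt


# --------------------------------------------------------------------------
# confusion_from_overlay
# --------------------------------------------------------------------------

def test_perfect_prediction_is_diagonal():
    gt = np.zeros((20, 20), dtype=np.uint8)
    gt[:10, :10] = 1  # 100 AC pixels
    tmap, gtm = make_pair([[1, 0], [0, 0]], gt)
    cm = confusion_from_overlay(tmap, gtm)
    assert cm.counts[0, 0] == 100
    assert cm.counts.sum() == 100


def test_all_wrong_prediction_zeroes_f1():
    gt = np.zeros((20, 20), dtype=np.uint8)
    gt[:10, :10] = 1
    tmap, gtm = make_pair([[5, 0], [0, 0]], gt)  # AC region predicted NT
    cm = confusion_from_overlay(tmap, gtm)
    assert cm.counts[0, 4] == 100
    assert metrics(cm).f1[GrowthPattern.AC] == 0.0


def test_polygon_spanning_two_tiles():
    """A 15x10 ground-truth band over tiles predicted (AC, SO) splits
    100 / 50 between the two columns."""
    gt = np.zeros((20, 20), dtype=np.uint8)
    gt[0:10, 0:15] = 1
    tmap, gtm = make_pair([[1, 3], [0, 0]], gt)
    cm = confusion_from_overlay(tmap, gtm)
    assert cm.counts[0, 0] == 100
    assert cm.counts[0, 2] == 50


def test_pixels_over_background_tiles_counted_separately():
    gt = np.zeros((20, 20), dtype=np.uint8)
    gt[:, :] = 5
    tmap, gtm = make_pair([[3, 0], [0, 0]], gt)
    cm = confusion_from_overlay(tmap, gtm)
    assert cm.counts.sum() == 100  # only the classified tile's pixels
    assert cm.unclassified[4] == 300  # NT pixels over unclassified tiles


def test_overlay_matches_per_pixel_oracle(rng):
    """50 random small map/mask pairs tally identically to an explicit
    per-pixel loop."""
    for _ in range(50):
        rows, cols = rng.integers(2, 6, 2)
        tile_px = int(rng.integers(4, 9))
        ds = int(rng.choice([1, 2]))
        map_labels = rng.integers(0, 6, (rows, cols)).astype(np.uint8)
        gh = -(-rows * tile_px // ds)
        gw = -(-cols * tile_px // ds)
        gt_labels = rng.integers(0, 6, (gh, gw)).astype(np.uint8)
        tmap, gtm = make_pair(map_labels, gt_labels, tile_px, ds)
        cm = confusion_from_overlay(tmap, gtm)
        expected = np.zeros((5, 5), dtype=int)
        unclassified = np.zeros(5, dtype=int)
        for i in range(gh):
            for j in range(gw):
                t = gt_labels[i, j]
                if t == 0:
                    continue
                r = int((i + 0.5) * ds // tile_px)
                c = int((j + 0.5) * ds // tile_px)
                p = map_labels[r, c] if r < rows and c < cols else 0
                if p == 0:
                    unclassified[t - 1] += 1
                else:
                    expected[t - 1, p - 1] += 1
        np.testing.assert_array_equal(cm.counts, expected)
        np.testing.assert_array_equal(cm.unclassified, unclassified)


def test_frame_mismatch_rejected():
    tmap = TumorMap(labels=np.zeros((4, 4), dtype=np.uint8), tile_px=10)
    gt = GroundTruthMask(np.zeros((10, 10), dtype=np.uint8), downsample=1)
    with pytest.raises(ValueError):
        confusion_from_overlay(tmap, gt)


# --------------------------------------------------------------------------
# aggregate and metrics
# --------------------------------------------------------------------------

def test_aggregate_with_zero_matrix_is_identity(rng):
    m = ConfusionMatrix(rng.integers(0, 50, (5, 5)))
    z = ConfusionMatrix(np.zeros((5, 5), dtype=int))
    np.testing.assert_array_equal(aggregate([m, z]).counts, m.counts)


def test_aggregate_sums_and_is_order_invariant(rng):
    ms = [ConfusionMatrix(rng.integers(0, 50, (5, 5))) for _ in range(3)]
    total = aggregate(ms).counts
    np.testing.assert_array_equal(total, sum(m.counts for m in ms))
    np.testing.assert_array_equal(aggregate(ms[::-1]).counts, total)


def test_aggregate_empty_rejected():
    with pytest.raises(ValueError):
        aggregate([])


def test_diagonal_matrix_perfect_metrics():
    rep = metrics(ConfusionMatrix(np.diag([10, 20, 30, 40, 50])))
    assert rep.accuracy == 1.0
    assert all(f == 1.0 for f in rep.f1.values())


def test_metrics_match_closed_formula():
    counts = np.diag([100, 100, 100, 100, 100])
    counts[0] = [50, 50, 0, 0, 0]  # half of AC truth predicted MP
    rep = metrics(ConfusionMatrix(counts))
    # AC: TP=50, FN=50, FP=0 -> F1 = 2*50/(2*50+0+50)
    assert rep.f1[GrowthPattern.AC] == pytest.approx(100 / 150)
    # MP: TP=100, FP=50, FN=0 -> F1 = 200/250
    assert rep.f1[GrowthPattern.MP] == pytest.approx(200 / 250)
    assert rep.accuracy == pytest.approx(450 / 500)


def test_single_off_diagonal_entry_acc_zero():
    counts = np.zeros((5, 5), dtype=int)
    counts[0, 1] = 7
    rep = metrics(ConfusionMatrix(counts))
    assert rep.accuracy == 0.0


def test_study_metrics_equal_pooled_pixel_metrics(rng):
    """Metrics of the aggregated matrix equal metrics recomputed from the
    pooled per-pixel records across slides."""
    pixel_records = []
    mats = []
    for _ in range(4):
        truth = rng.integers(1, 6, 200)
        pred = rng.integers(1, 6, 200)
        pixel_records.append((truth, pred))
        counts = np.zeros((5, 5), dtype=int)
        np.add.at(counts, (truth - 1, pred - 1), 1)
        mats.append(ConfusionMatrix(counts))
    study = metrics(aggregate(mats))
    truth = np.concatenate([t for t, _ in pixel_records])
    pred = np.concatenate([p for _, p in pixel_records])
    pooled = np.zeros((5, 5), dtype=int)
    np.add.at(pooled, (truth - 1, pred - 1), 1)
    pooled_rep = metrics(ConfusionMatrix(pooled))
    assert study.accuracy == pooled_rep.accuracy
    assert study.f1 == pooled_rep.f1


def test_all_zero_matrix_rejected():
    with pytest.raises(ValueError):
        metrics(ConfusionMatrix(np.zeros((5, 5), dtype=int)))


# --------------------------------------------------------------------------
# tumor vs non-tumor merge
# --------------------------------------------------------------------------

def test_merge_diagonal_perfect():
    m2, rep = merge_tumor_vs_nontumor(ConfusionMatrix(np.diag([1, 2, 3, 4, 5])))
    assert rep["accuracy"] == 1.0
    np.testing.assert_array_equal(m2, [[10, 0], [0, 5]])


def test_within_tumor_confusion_is_correct_after_merge():
    counts = np.zeros((5, 5), dtype=int)
    counts[0, 1] = 100  # all AC predicted MP
    _, rep = merge_tumor_vs_nontumor(ConfusionMatrix(counts))
    assert rep["accuracy"] == 1.0


def test_merge_matches_block_summation_oracle(rng):
    counts = rng.integers(0, 30, (5, 5))
    m2, _ = merge_tumor_vs_nontumor(ConfusionMatrix(counts))
    assert m2[0, 0] == counts[:4, :4].sum()
    assert m2[0, 1] == counts[:4, 4].sum()
    assert m2[1, 0] == counts[4, :4].sum()
    assert m2[1, 1] == counts[4, 4]


# --------------------------------------------------------------------------
# rank tests
# --------------------------------------------------------------------------

def test_rank_sum_identical_samples_p_one():
    _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == pytest.approx(1.0, abs=0.05)


def test_rank_sum_complete_separation_exact_p():
    """3 vs 3 fully separated samples: the two extreme assignments of
    C(6,3)=20 give exact two-sided p = 2/20 = 0.1, confirmed here by full
    enumeration."""
    a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
    _, p = wilcoxon_rank_sum(a, b)
    # independent enumeration of all rank assignments
    observed = sum(sorted(a + b).index(x) + 1 for x in a)
    more_extreme = 0
    total = 0
    for combo in itertools.combinations(range(1, 7), 3):
        total += 1
        s = sum(combo)
        if abs(s - 10.5) >= abs(observed - 10.5):
            more_extreme += 1
    assert p == pytest.approx(more_extreme / total)
    assert p == pytest.approx(0.1)


def test_rank_sum_shift_invariance(rng):
    a, b = rng.normal(size=8).tolist(), rng.normal(size=9).tolist()
    s1, p1 = wilcoxon_rank_sum(a, b)
    s2, p2 = wilcoxon_rank_sum([x + 5 for x in a], [x + 5 for x in b])
    assert s1 == s2 and p1 == pytest.approx(p2)


def test_rank_sum_empty_rejected():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


def test_signed_rank_all_zero_differences_vacuous():
    with pytest.warns(UserWarning):
        _, p = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
    assert p == 1.0


def test_signed_rank_six_positive_pairs_exact_p():
    """Six all-positive differences of distinct magnitude: the sign
    enumeration gives two extreme outcomes of 2^6, p = 0.03125."""
    a = [2.0, 4.0, 6.0, 8.0, 10.0, 12.0]
    b = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    _, p = wilcoxon_signed_rank(a, b)
    assert p == pytest.approx(2 / 2**6)


def test_signed_rank_direction_symmetry(rng):
    a = rng.normal(1, 1, size=10).tolist()
    b = rng.normal(0, 1, size=10).tolist()
    _, p_ab = wilcoxon_signed_rank(a, b)
    _, p_ba = wilcoxon_signed_rank(b, a)
    assert p_ab == pytest.approx(p_ba)


def test_signed_rank_length_mismatch_rejected():
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([1.0], [1.0, 2.0])
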