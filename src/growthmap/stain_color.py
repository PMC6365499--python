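"""Reinhard color transfer in the decorrelated log-chromatic lab space.

H&E staining hue varies between and within laboratories.  The transfer
technique of Reinhard et al. matches the per-channel mean and standard
deviation of an image to a target in lab — a log-chromatic space whose
axes are approximately decorrelated for natural images: RGB is mapped to
LMS cone responses, logarithms are taken, and a fixed linear transform
yields an achromatic axis (l) and two opponent-chromatic axes (alpha:
yellow-blue, beta: red-green).  Matching first and second moments channel
by channel in this space transfers the overall color appearance while
preserving structure.

Target color patterns are derived from training-tile corpora by k-means
clustering of lab pixel vectors; each cluster's per-channel mean/std
defines one reusable pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabStats",
    "ColorPattern",
    "to_lab",
    "from_lab",
    "reinhard_transfer",
    "normalize_tile",
    "derive_color_patterns",
    "save_patterns",
    "load_patterns",
]

# RGB -> LMS cone-response matrix (Reinhard et al. 2001).
_RGB2LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)
# Exact inverse rather than the commonly printed 4-decimal rounding of it:
# the rounded matrix costs up to 2 intensity levels on saturated pixels,
# which would break the within-one-level round-trip guarantee.
_LMS2RGB = np.linalg.inv(_RGB2LMS)
# log-LMS -> lab decorrelating transform: diagonal scaling times the
# achromatic / yellow-blue / red-green mixing matrix.
_LOGLMS2LAB = np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)]) @ np.array(
    [[1, 1, 1], [1, 1, -2], [1, -1, 0]], dtype=float
)
_LAB2LOGLMS = np.linalg.inv(_LOGLMS2LAB)

#: Clamp for LMS values before the log (black pixels would otherwise map
#: to -inf); expressed on the [0, 1] intensity scale.
LMS_EPS = 1e-6


@dataclass
class LabStats:
    """Per-channel mean and standard deviation in lab (dimensionless)."""

    mean: np.ndarray  # (3,) order (l, alpha, beta)
    std: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.mean.shape != (3,) or self.std.shape != (3,):
            raise ValueError("LabStats mean/std must be length-3 vectors")
        if (self.std < 0).any():
            raise ValueError("standard deviations must be non-negative")

    @classmethod
    def from_lab_image(cls, lab: np.ndarray) -> "LabStats":
        flat = lab.reshape(-1, 3)
        return cls(flat.mean(axis=0), flat.std(axis=0))

    @classmethod
    def from_rgb_image(cls, rgb: np.ndarray) -> "LabStats":
        return cls.from_lab_image(to_lab(rgb))


@dataclass
class ColorPattern:
    """A reusable Reinhard transfer target with provenance.

    ``provenance`` records which corpus/cluster produced the pattern (e.g.
    a training cohort name).
    """

    stats: LabStats
    pattern_id: str
    provenance: str = ""


def to_lab(rgb: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB raster to lab (float, same spatial shape).

    RGB is scaled to [0, 1], mapped through the LMS cone matrix, logged
    (base 10, with a small clamp so black stays finite) and decorrelated.
    """
    s = np.asarray(rgb, dtype=float)[..., :3] / 255.0
    lms = s @ _RGB2LMS.T
    log_lms = np.log10(np.maximum(lms, LMS_EPS))
    return log_lms @ _LOGLMS2LAB.T


def from_lab(lab: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_lab`; output clipped to 8-bit RGB."""
    log_lms = np.asarray(lab, dtype=float) @ _LAB2LOGLMS.T
    lms = np.power(10.0, log_lms)
    s = lms @ _LMS2RGB.T
    return np.clip(np.round(s * 255.0), 0, 255).astype(np.uint8)


def reinhard_transfer(
    tile: np.ndarray,
    target_stats: LabStats,
    source_stats: LabStats | None = None,
    eps: float = 1e-6,
) -> np.ndarray:
    """Match a tile's lab channel statistics to a target.

    Per channel c: ``out = (in - mean_src_c) * std_tgt_c / max(std_src_c, eps)
    + mean_tgt_c``.  A constant (zero-variance) source channel collapses to
    the target mean through the eps guard.
    """
    lab = to_lab(tile)
    src = source_stats if source_stats is not None else LabStats.from_lab_image(lab)
    scale = target_stats.std / np.maximum(src.std, eps)
    out = (lab - src.mean) * scale + target_stats.mean
    return from_lab(out)


def normalize_tile(tile: np.ndarray, target: ColorPattern) -> np.ndarray:
    """Reinhard-normalize a tile to a target pattern, using the tile's own
    statistics as the source."""
    return reinhard_transfer(tile, target.stats)


# --------------------------------------------------------------------------
# Pattern derivation
# --------------------------------------------------------------------------

def _corpus_pixels(tiles, subsample: int, rng: np.random.Generator) -> np.ndarray:
    pixels = np.concatenate([np.asarray(t).reshape(-1, 3) for t in tiles])
    if len(pixels) > subsample:
        idx = rng.choice(len(pixels), size=subsample, replace=False)
        pixels = pixels[idx]
    return pixels


def derive_color_patterns(
    corpora: dict[str, list[np.ndarray]],
    k_total: int = 4,
    seed: int = 0,
    subsample_per_corpus: int = 100_000,
    max_iter: int = 300,
) -> list[ColorPattern]:
    """Derive ``k_total`` transfer targets by k-means over corpus pixels.

    Each corpus (e.g. one staining cohort) is clustered separately in lab,
    with ``k_total`` split as evenly as possible across corpora (two corpora
    and k_total=4 give 2 clusters each).  Every cluster contributes one
    pattern from its members' per-channel mean and std.  Deterministic for
    a fixed seed; clusters within a corpus are ordered by luminance mean.
    """
    from sklearn.cluster import KMeans

    if not corpora:
        raise ValueError("at least one corpus is required")
    for name, tiles in corpora.items():
        if not tiles:
            raise ValueError(f"corpus {name!r} is empty")
    n_corpora = len(corpora)
    if k_total < n_corpora:
        raise ValueError("k_total must be >= number of corpora")
    base, extra = divmod(k_total, n_corpora)
    rng = np.random.default_rng(seed)
    patterns: list[ColorPattern] = []
    for idx, (name, tiles) in enumerate(corpora.items()):
        k = base + (1 if idx < extra else 0)
        pixels = _corpus_pixels(tiles, subsample_per_corpus, rng)
        lab = to_lab(pixels.reshape(-1, 1, 3)).reshape(-1, 3)
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=10,
            max_iter=max_iter,
            random_state=int(rng.integers(2**31)),
        ).fit(lab)
        order = np.argsort(km.cluster_centers_[:, 0])
        for rank, cluster in enumerate(order):
            members = lab[km.labels_ == cluster]
            stats = LabStats(members.mean(axis=0), members.std(axis=0))
            patterns.append(
                ColorPattern(stats, pattern_id=f"{name}-{rank}", provenance=name)
            )
    return patterns


def pooled_stats(corpora: dict[str, list[np.ndarray]], subsample: int = 100_000, seed: int = 0) -> LabStats:
    """lab statistics of the pooled corpus — the default inference-time
    normalization target."""
    rng = np.random.default_rng(seed)
    pixels = np.concatenate(
        [_corpus_pixels(tiles, subsample, rng) for tiles in corpora.values()]
    )
    return LabStats.from_lab_image(to_lab(pixels.reshape(-1, 1, 3)))


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def save_patterns(patterns: list[ColorPattern], path) -> None:
    payload = [
        {
            "pattern_id": p.pattern_id,
            "mean": p.stats.mean.tolist(),
            "std": p.stats.std.tolist(),
            "provenance": p.provenance,
        }
        for p in patterns
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_patterns(path) -> list[ColorPattern]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        ColorPattern(
            LabStats(np.array(d["mean"]), np.array(d["std"])),
            pattern_id=d["pattern_id"],
            provenance=d.get("provenance", ""),
        )
        for d in payload
    ]
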