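"""Pluggable tile classifiers: the contract, a rule-based reference
classifier for synthetic textures, and a small trainable backend.

Every classifier maps a list of RGB tile rasters to one probability vector
per tile over the five tissue classes (AC, MP, SO, CR, NT), entries
summing to 1.  The pipeline only relies on this contract, so deep models
can be swapped in; the rule-based classifier keys interpretable
morphological features (foreground fraction, connected components, lumina
per component, component size) to the synthetic texture families, making
the whole pipeline exercisable deterministically at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.transform import resize_local_mean

from .classes import ALL_CLASSES, GrowthPattern
from .tissue_masking import luma

__all__ = [
    "ClassifierConfig",
    "TileClassifier",
    "check_probabilities",
    "preprocess_tile",
    "standardize_batch",
    "classify_batch",
    "MockClassifier",
    "mock_classifier",
    "TrainedTileModel",
    "train_tile_classifier",
    "get_backend",
]

N_CLASSES = len(ALL_CLASSES)


@dataclass
class ClassifierConfig:
    """Backend-independent classifier settings.

    ``input_px`` is the model input edge length; tiles are area-resampled
    to it before classification.  The training defaults (learning rate,
    epochs, batch size) apply only to trainable backends.
    """

    input_px: int = 256
    backend: str = "mock"
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_px <= 0:
            raise ValueError("input_px must be positive")


class TileClassifier(Protocol):
    def predict_proba(self, tiles: Sequence[np.ndarray]) -> np.ndarray: ...


def check_probabilities(p: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    """Validate an (n, 5) matrix of class probabilities."""
    p = np.asarray(p, dtype=float)
    if p.ndim == 1:
        p = p[None, :]
    if p.shape[1] != N_CLASSES:
        raise ValueError(f"probability vectors must have {N_CLASSES} entries")
    if (p < -atol).any() or np.abs(p.sum(axis=1) - 1.0).max(initial=0) > atol:
        raise ValueError("classifier output is not a valid probability vector")
    return p


def preprocess_tile(tile: np.ndarray, input_px: int = 256) -> np.ndarray:
    """Area-style resample a square RGB tile to the model input size."""
    tile = np.asarray(tile)
    if tile.shape[0] != tile.shape[1]:
        raise ValueError("classifier input tiles must be square")
    if tile.shape[0] == input_px:
        return tile.astype(float)
    return resize_local_mean(tile.astype(float), (input_px, input_px, tile.shape[2]))


def standardize_batch(batch: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Zero-mean / unit-variance per channel over a batch of rasters."""
    batch = np.asarray(batch, dtype=float)
    mean = batch.mean(axis=(0, 1, 2), keepdims=True)
    std = batch.std(axis=(0, 1, 2), keepdims=True)
    return (batch - mean) / np.maximum(std, eps)


def classify_batch(tiles: Sequence[np.ndarray], model: TileClassifier) -> np.ndarray:
    """Classify a batch of tiles, enforcing the probability contract."""
    if len(tiles) == 0:
        return np.zeros((0, N_CLASSES))
    return check_probabilities(model.predict_proba(tiles))


# --------------------------------------------------------------------------
# Rule-based reference classifier
# --------------------------------------------------------------------------

@dataclass
class TileFeatures:
    """Interpretable morphology of a thresholded tile."""

    foreground_fraction: float
    n_components: int
    mean_component_area: float
    mean_holes_per_component: float


@dataclass
class MockClassifier:
    """Deterministic classifier keyed to the synthetic texture families.

    Features are computed on the dark-foreground mask (gray < ``luma_threshold``;
    pale non-tumor elements stay above it) and mapped through fixed decision
    rules:

    * near-zero foreground → NT (pale/benign texture or blank background);
    * >= ``cr_min_holes`` lumina per component → CR (perforated nests);
    * >= ``ac_min_holes`` lumina per component → AC (single-lumen glands);
    * otherwise large solid components → SO, small scattered ones → MP.

    The winner receives ``sharpness`` probability, the rest split the
    remainder evenly; lowering ``sharpness`` lets soft-voting experiments
    control disagreement.
    """

    luma_threshold: float = 180.0
    min_foreground_fraction: float = 0.02
    min_component_area: int = 12
    cr_min_holes: float = 1.5
    ac_min_holes: float = 0.35
    so_min_area: float = 250.0
    sharpness: float = 0.9

    def features(self, tile: np.ndarray) -> TileFeatures:
        fg = luma(tile) < self.luma_threshold
        frac = float(fg.mean())
        labeled = cc_label(fg, connectivity=2)
        props = [p for p in regionprops(labeled) if p.area >= self.min_component_area]
        if not props:
            return TileFeatures(frac, 0, 0.0, 0.0)
        areas = np.array([p.area for p in props], dtype=float)
        # Euler number of a component is 1 - (number of enclosed lumina).
        holes = np.array([1 - p.euler_number for p in props], dtype=float)
        return TileFeatures(frac, len(props), float(areas.mean()), float(holes.mean()))

    def classify_one(self, tile: np.ndarray) -> GrowthPattern:
        f = self.features(tile)
        if f.foreground_fraction < self.min_foreground_fraction or f.n_components == 0:
            return GrowthPattern.NT
        if f.mean_holes_per_component >= self.cr_min_holes:
            return GrowthPattern.CR
        if f.mean_holes_per_component >= self.ac_min_holes:
            return GrowthPattern.AC
        if f.mean_component_area >= self.so_min_area:
            return GrowthPattern.SO
        return GrowthPattern.MP

    def predict_proba(self, tiles: Sequence[np.ndarray]) -> np.ndarray:
        out = np.full((len(tiles), N_CLASSES), (1.0 - self.sharpness) / (N_CLASSES - 1))
        for i, tile in enumerate(tiles):
            out[i, int(self.classify_one(tile)) - 1] = self.sharpness
        return out


def mock_classifier(tile: np.ndarray, **kwargs) -> np.ndarray:
    """Classify one tile with the rule-based classifier; returns a length-5
    probability vector."""
    return MockClassifier(**kwargs).predict_proba([tile])[0]


# --------------------------------------------------------------------------
# Trainable backend
# --------------------------------------------------------------------------

_FEATURE_PX = 48  # downsized edge at which convolutional features are read
_N_FILTERS = 16
_FILTER_PX = 7


def _filter_bank(seed: int) -> list[np.ndarray]:
    # filters are a deterministic function of the training seed
    rng = np.random.default_rng(seed + 7919)
    return [rng.normal(0, 1, (_FILTER_PX, _FILTER_PX)) / _FILTER_PX
            for _ in range(_N_FILTERS)]


def _conv_features(tiles: Sequence[np.ndarray], filters: list[np.ndarray]) -> np.ndarray:
    from scipy import ndimage

    feats = []
    for tile in tiles:
        small = resize_local_mean(
            np.asarray(tile, dtype=float) / 255.0, (_FEATURE_PX, _FEATURE_PX, 3)
        )
        gray = small @ np.array([0.299, 0.587, 0.114])
        row = []
        for f in filters:
            act = np.maximum(ndimage.convolve(gray, f, mode="reflect"), 0.0)
            row += [act.mean(), act.std(), float((act > 0.1).mean())]
        feats.append(row)
    return np.asarray(feats)


@dataclass
class TrainedTileModel:
    """A fitted compact convolutional tile classifier.

    A bank of fixed, seed-derived random convolution filters with ReLU and
    pooled activation statistics feeds a trained multilayer-perceptron
    readout.  Feature standardization moments are stored so inference is a
    pure function of the saved state.  Columns for classes absent from the
    training data are zero-filled.
    """

    estimator: object
    filters: list = field(default_factory=list)
    feat_mean: np.ndarray = field(default=None)
    feat_std: np.ndarray = field(default=None)

    def predict_proba(self, tiles: Sequence[np.ndarray]) -> np.ndarray:
        X = (_conv_features(tiles, self.filters) - self.feat_mean) / self.feat_std
        raw = self.estimator.predict_proba(X)
        out = np.zeros((len(tiles), N_CLASSES))
        for col, cls in enumerate(self.estimator.classes_):
            out[:, int(cls) - 1] = raw[:, col]
        # re-normalize against numerical drift
        out /= out.sum(axis=1, keepdims=True)
        return out


def train_tile_classifier(
    tiles: Sequence[np.ndarray],
    labels: Sequence[GrowthPattern | int],
    cfg: ClassifierConfig | None = None,
) -> TrainedTileModel:
    """Train the compact convolutional backend on labeled tiles.

    Seeded and reproducible: the same tiles, labels and config yield
    identical predictions.  Raises on an empty training set.
    """
    from sklearn.neural_network import MLPClassifier

    if len(tiles) == 0:
        raise ValueError("training set is empty")
    if len(tiles) != len(labels):
        raise ValueError("tiles and labels differ in length")
    cfg = cfg or ClassifierConfig(backend="convnet")
    filters = _filter_bank(cfg.seed)
    X = _conv_features(tiles, filters)
    mean = X.mean(axis=0)
    std = X.std(axis=0) + 1e-8
    y = np.array([int(l) for l in labels])
    est = MLPClassifier(
        hidden_layer_sizes=(64,),
        learning_rate_init=cfg.learning_rate,
        max_iter=500,
        batch_size=min(cfg.batch_size, len(tiles)),
        random_state=cfg.seed,
    )
    est.fit((X - mean) / std, y)
    return TrainedTileModel(est, filters=filters, feat_mean=mean, feat_std=std)


def get_backend(name: str, **kwargs) -> TileClassifier:
    """Model registry keyed by backend name."""
    if name == "mock":
        return MockClassifier(**kwargs)
    raise ValueError(
        f"unknown classifier backend {name!r}; trainable models are produced "
        "by train_tile_classifier and passed as objects"
    )
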