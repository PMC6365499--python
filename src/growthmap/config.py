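"""Layered pipeline configuration (defaults < file < flags).

All tunable defaults of the pipeline live here: the tissue-mask threshold
(230 on the 8-bit gray scale at ~5x), the tile-retention cutoff (20%
tissue), the reference tile geometry (600 px at 0.5 um/px, i.e. a 20x
scan), the soft-vote neighborhood (N = 9, uniform weights, 1/3-edge
shifts), the classifier input size (256 px) and the number of color
patterns (4).  Seeds are mandatory for any stochastic path — absent seeds
are a validation error, never silent nondeterminism.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass
class PipelineConfig:
    # tissue masking
    mask_threshold: float = 230.0
    min_tissue_fraction: float = 0.20
    mask_magnification: float = 5.0
    closing_size: int = 5
    # tiling
    reference_tile_px: int = 600
    reference_pixel_size_um: float = 0.5
    # color
    k_patterns: int = 4
    label_attribute: str = "Text"
    # contextual voting
    neighborhood: int = 9
    shift_fraction: float = 1.0 / 3.0
    # classifier
    input_px: int = 256
    backend: str = "mock"
    # reproducibility
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.mask_threshold <= 255:
            raise ValueError("mask_threshold must be in [0, 255]")
        if not 0 < self.min_tissue_fraction <= 1:
            raise ValueError("min_tissue_fraction must be in (0, 1]")
        if self.reference_tile_px <= 0 or self.reference_pixel_size_um <= 0:
            raise ValueError("reference tile geometry must be positive")
        if not 0 < self.shift_fraction < 1:
            raise ValueError("shift_fraction must be in (0, 1)")
        if self.neighborhood < 1 or self.input_px <= 0 or self.k_patterns < 1:
            raise ValueError("invalid pipeline configuration")

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError(
                "this operation is stochastic; set an explicit seed in the config"
            )
        return int(self.seed)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from defaults, an optional YAML file, and overrides.

    Unknown keys in the file or the overrides are rejected.
    """
    known = {f.name for f in fields(PipelineConfig)}
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(data)
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
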