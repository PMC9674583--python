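"""Pipeline configuration.

All tunables of the analysis live here, grouped the way the pipeline stages
consume them: grid tiling, GLCM texture, and group statistics. A single YAML
(or JSON) file maps onto :class:`PipelineConfig`; every field has the
documented default so a minimal config only needs a ``stats.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

#: The 12 co-occurrence offsets used for texture analysis, written as
#: (dx, dy) = (column shift, row shift): 4 distances at each of the three
#: angles 0°, 45° and 90°.
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1), (0, 2), (0, 3), (0, 4),
    (1, 0), (2, 0), (3, 0), (4, 0),
    (1, 1), (2, 2), (3, 3), (4, 4),
)

#: Feature columns compared between groups by default. ``homogeneity`` is
#: stored in the feature table but excluded here because heterogeneity is its
#: complement (identical rank test, negated effect).
DEFAULT_FEATURES: tuple[str, ...] = (
    "patch_count",
    "mean_patch_area_px",
    "mean_fg_intensity",
    "mean_intensity_per_patch",
    "energy",
    "contrast",
    "heterogeneity",
)


@dataclass
class GridConfig:
    """Fixed-size grid tiling of each image, anchored at the top-left corner.

    block_size_px : edge length of a grid block in pixels. 100 px at the
        25 nm sampling of the imaging regime gives ~2.5 µm blocks.
    include_truncated_edge_blocks : whether the right/bottom remainder tiles
        (smaller than block_size_px) enter the analysis. Off by default so
        every analysed block has identical area.
    """

    block_size_px: int = 100
    include_truncated_edge_blocks: bool = False

    def __post_init__(self) -> None:
        if self.block_size_px < 8:
            raise ValueError(f"block_size_px must be >= 8, got {self.block_size_px}")


@dataclass
class GlcmConfig:
    """Gray-level co-occurrence settings.

    levels : number of gray levels after quantization.
    quantization : 'block_minmax' bins each block over its own intensity
        range; 'global_range' bins over ``global_range`` for all blocks.
    symmetric : accumulate each pixel pair in both orders (required for exact
        180-degree rotation robustness).
    homogeneity_form : 'squared' uses 1/(1+(i-j)^2) (inverse difference
        moment), 'abs' uses 1/(1+|i-j|).
    offsets : (dx, dy) co-occurrence displacements.
    """

    levels: int = 64
    quantization: str = "block_minmax"
    global_range: tuple[float, float] = (0.0, 65535.0)
    symmetric: bool = True
    homogeneity_form: str = "squared"
    offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if self.quantization not in ("block_minmax", "global_range"):
            raise ValueError(f"unknown quantization mode {self.quantization!r}")
        if self.homogeneity_form not in ("squared", "abs"):
            raise ValueError(f"unknown homogeneity_form {self.homogeneity_form!r}")
        self.offsets = tuple((int(dx), int(dy)) for dx, dy in self.offsets)
        if not self.offsets:
            raise ValueError("offsets must be non-empty")
        if (0, 0) in self.offsets:
            raise ValueError("offset (0, 0) is not a valid co-occurrence displacement")


@dataclass
class StatsConfig:
    """Group-comparison settings.

    n_boot : bootstrap resamples for median-difference CIs and SE(median).
    ci_level : two-sided confidence level of the percentile bootstrap CI.
    seed : master seed for every stochastic step (mandatory for runs).
    pooling : 'block' pools all selected blocks of a group into one sample;
        'image' first averages features per image.
    correction : multiple-testing correction across features
        ('none', 'bonferroni', 'fdr_bh').
    """

    n_boot: int = 10_000
    ci_level: float = 0.95
    seed: int = 0
    pooling: str = "block"
    correction: str = "none"
    features: Sequence[str] = DEFAULT_FEATURES

    def __post_init__(self) -> None:
        if self.n_boot < 100:
            raise ValueError(f"n_boot must be >= 100, got {self.n_boot}")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.pooling not in ("block", "image"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.correction not in ("none", "bonferroni", "fdr_bh"):
            raise ValueError(f"unknown correction {self.correction!r}")
        self.features = tuple(self.features)


@dataclass
class PipelineConfig:
    grid: GridConfig = field(default_factory=GridConfig)
    glcm: GlcmConfig = field(default_factory=GlcmConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    pixel_size_nm: float = 25.0
    min_patch_area_px: int = 1

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.min_patch_area_px < 1:
            raise ValueError("min_patch_area_px must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["glcm"]["offsets"] = [list(o) for o in self.glcm.offsets]
        d["glcm"]["global_range"] = list(self.glcm.global_range)
        d["stats"]["features"] = list(self.stats.features)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        grid = GridConfig(**d.pop("grid", {}))
        glcm_d = dict(d.pop("glcm", {}))
        if "offsets" in glcm_d:
            glcm_d["offsets"] = [tuple(o) for o in glcm_d["offsets"]]
        if "global_range" in glcm_d:
            glcm_d["global_range"] = tuple(glcm_d["global_range"])
        glcm = GlcmConfig(**glcm_d)
        stats = StatsConfig(**d.pop("stats", {}))
        return cls(grid=grid, glcm=glcm, stats=stats, **d)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return PipelineConfig.from_dict(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
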