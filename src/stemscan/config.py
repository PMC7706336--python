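"""Run configuration: site geometry and pipeline constants.

The pipeline defaults are the standard post-processing constants for this
kind of imagery: 1000-px patches at 50 % overlap, cross-patch duplicate
elimination at 0.75 overlap fraction, a 0.80 confidence cut, detection
evaluation at IOU 0.5 and candidate NMS at IOU 0.2. Every run logs the
resolved configuration so results are reproducible from config + seed.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["SiteConfig", "PipelineConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class SiteConfig:
    row_spacing: float = 0.17  # m
    ground_resolution: float = 0.18  # mm/px
    sampled_area: float | None = None  # m² per image; image extent when None
    images_per_plot: int = 1


@dataclass(frozen=True)
class PipelineConfig:
    patch_size: int = 1000
    overlap: float = 0.5
    merge_overlap: float = 0.75
    score_threshold: float = 0.80
    iou_eval: float = 0.5
    nms_iou: float = 0.2
    smooth_sigma: float = 0.0  # optional profile smoothing, sample units


@dataclass(frozen=True)
class RunConfig:
    site: SiteConfig = field(default_factory=SiteConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    seed: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path=None) -> RunConfig:
    """Load a RunConfig from a TOML or YAML file; defaults when path is None."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if path.suffix.lower() == ".toml":
        data = tomllib.loads(path.read_text())
    else:
        data = yaml.safe_load(path.read_text()) or {}
    site = SiteConfig(**data.get("site", {}))
    pipeline = PipelineConfig(**data.get("pipeline", {}))
    return RunConfig(site=site, pipeline=pipeline, seed=int(data.get("seed", 0)))
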