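"""Pipeline configuration: a YAML-serializable bundle of paths and parameters."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .surface_maps import (DEFAULT_MEDIAN_PATCH, DEFAULT_PIXEL_SIZE,
                           DEFAULT_PLANT_THRESHOLD)

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; round-trips through YAML."""

    # paths
    scan_paths: list[str] = field(default_factory=list)
    sphere_paths: list[str] = field(default_factory=list)
    soil_scan_path: str | None = None
    soil_map_path: str | None = None
    reference_sphere_path: str | None = None  # default: first scan defines the frame
    output_dir: str = "out"
    roi_csv: str | None = None

    # grid
    grid_origin: tuple[float, float] = (0.0, 0.0)
    grid_extent: tuple[float, float] = (10.0, 10.0)  # width, height in m
    pixel_size: float = DEFAULT_PIXEL_SIZE
    median_patch: float = DEFAULT_MEDIAN_PATCH

    # analysis
    plant_threshold: float = DEFAULT_PLANT_THRESHOLD
    approaches: list[str] = field(default_factory=lambda: ["FA_ALLPOINTS"])
    percentiles: list[int] = field(default_factory=lambda: list(range(90, 101)))
    patch_size: tuple[float, float] = (0.10, 0.10)
    reference_percentile: int = 99
    growth_mode: str = "consecutive"  # or "same_hour" for soybean-like crops
    shd_bin_width: float = 0.05

    # simulation
    seed: int = 0
    scanner_height: float = 3.5
    resolution_fraction: float = 0.25
    range_noise_sd: float = 0.002
    outlier_rate: float = 0.0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        # YAML round-trips tuples as lists; normalize back
        cfg.grid_origin = tuple(cfg.grid_origin)
        cfg.grid_extent = tuple(cfg.grid_extent)
        cfg.patch_size = tuple(cfg.patch_size)
        return cfg

    def digest(self) -> str:
        """Short stable hash of the config, stamped into output headers."""
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
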