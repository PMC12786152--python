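"""Pipeline configuration with YAML round-tripping.

Defaults encode the pipeline's standard operating point: resize images
above 1000 px by 0.5 and again when ppd > 50; ISODATA from the global
mean with tolerance 1e-6 capped at 100 iterations; 20 px small-object
cleanup; Sato vesselness at scales 1-3 px with response threshold 0.15;
disk(2) closings; optic disc diameter assumed 5 degrees with Hough radius
factors 0.5-2.5; start-band margin delta = 5 px; pixel-count arc mode;
alpha = 0.05 for the Shapiro gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    fov_deg: float = 45.0
    resize_max_dim: int = 1000
    resize_factor: float = 0.5
    ppd_limit: float = 50.0
    isodata_tol: float = 1e-6
    isodata_max_iter: int = 100
    min_object_px: int = 20
    invert_b: bool = False
    enhance_method: str = "vesselness"  # vesselness | none
    vesselness_scales: list = field(default_factory=lambda: [1, 2, 3])
    vesselness_threshold: float = 0.15
    closing_radius_restore: int = 2
    closing_radius_av: int = 2
    od_diameter_deg: float = 5.0
    od_radius_factors: list = field(default_factory=lambda: [0.5, 2.5])
    delta_px: float = 5.0
    arc_mode: str = "pixel"  # pixel | geometric
    polyline_stride: int = 5
    alpha: float = 0.05
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
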