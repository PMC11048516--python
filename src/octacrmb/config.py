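"""Run configuration: every parameter that affects a biomarker value.

The config is serialized into each run's provenance block so a run can be
reproduced bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import yaml


@dataclass
class RunConfig:
    width_mm: float = 3.0
    crop_box: tuple[int, int, int, int] | None = None
    fovea_center_rc: tuple[float, float] | None = None
    threshold_method: str = "local_mean"
    local_window_mm: float = 0.2
    local_offset_frac: float = 0.06
    intensity_threshold: float | None = None  # None = 80th percentile of vessels
    diameter_threshold_um: float = 25.0
    n_rays: int = 360
    fd_box_sizes: list[int] | None = None
    alpha_corr: float = 0.05
    alpha_group: float = 0.1
    lasso_folds: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if data.get("crop_box") is not None:
            data["crop_box"] = tuple(data["crop_box"])
        if data.get("fovea_center_rc") is not None:
            data["fovea_center_rc"] = tuple(data["fovea_center_rc"])
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
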