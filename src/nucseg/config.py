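"""One YAML-backed configuration object for the whole pipeline.

All tunable thresholds live here with their reference defaults: the
single-nucleus gates (area 309..7801 px, roundness 0.31..0.99), the
conditional-erosion thresholds (T1=350, T2=50), the matching thresholds
(Hausdorff 30 px, Jaccard 0.5), the incident light intensity i0=255 and
the adaptive-threshold window. Conventions that tests rely on are pinned
here too: Crofton perimeter estimation, population-variance patch
statistics, 8-connected component labeling.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .morphometrics import GatingRule
from .seeds import ErosionPolicy

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    i0: float = 255.0
    gating: GatingRule = field(default_factory=GatingRule)
    erosion: ErosionPolicy = field(default_factory=ErosionPolicy)
    hd_threshold: float = 30.0
    jd_threshold: float = 0.5
    adaptive_window: int = 51
    adaptive_offset: float = 0.0
    include_border_in_mask: bool = False
    connectivity: int = 8
    perimeter_estimator: str = "crofton"   # informational; pinned convention
    std_convention: str = "population"     # informational; pinned convention

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "gating" in data:
            data["gating"] = GatingRule(**data["gating"])
        if "erosion" in data:
            data["erosion"] = ErosionPolicy(**data["erosion"])
        return cls(**data)
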