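"""Analysis configuration: one structured file governs every threshold.

Every default equals the study procedure's stated value (500 m escape
radius, 2/5 km analysis radii, 5 km/h stop filter, α = 0.05), so a bare run
is the reference procedure.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class FollowingConfig:
    d_max_m: float = 100.0
    t_min_s: float = 120.0
    slack_s: float = 2.0


@dataclass
class AnalysisConfig:
    escape_radius_m: float = 500.0
    analysis_radii_m: tuple = (2000.0, 5000.0)
    min_speed_kmh: float = 5.0
    following: FollowingConfig = field(default_factory=FollowingConfig)
    alpha: float = 0.05
    seed: int = 0
    hei_anchor: str = "segment_start"   # or "release_point"
    unit_vectors: bool = False          # Hotelling on unit vectors instead of full mean vectors

    def to_dict(self) -> dict:
        d = asdict(self)
        d["analysis_radii_m"] = list(self.analysis_radii_m)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "following" in d and isinstance(d["following"], dict):
            d["following"] = FollowingConfig(**d["following"])
        if "analysis_radii_m" in d:
            d["analysis_radii_m"] = tuple(float(r) for r in d["analysis_radii_m"])
        return cls(**d)


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisConfig.from_dict(data)


def save_config(cfg: AnalysisConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
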