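"""Run configuration: every pipeline parameter in one place.

The config is a nested dataclass serialisable to/from YAML. Unknown keys are
rejected on load so typos cannot silently fall back to defaults, and every
output artifact records ``config_hash`` so results are traceable to the exact
parameter set that produced them.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "default_config"]


@dataclass
class PreprocessConfig:
    n_classes: int = 3
    smooth_radius_px: int = 5
    opening_radius_px: int = 1
    wiener_window: int = 5


@dataclass
class EnhanceConfig:
    dog_sigma_low_mm: float = 0.05   # 1 px at 0.05 mm/px
    dog_sigma_high_mm: float = 0.40  # 8 px


@dataclass
class DetectConfig:
    hog_sigma_mm: float = 0.10  # 2 px
    k_sigma: float = 5.0
    line_ratio: float = 0.25
    blobness_width: float = 0.5


@dataclass
class ClusterConfig:
    eps_mm: float = 5.0
    min_pts: int = 3
    min_area_px: int = 2
    max_area_px: int = 80
    max_eccentricity: float = 0.95
    line_veto: float = 0.5


@dataclass
class StatsConfig:
    n_boot: int = 1000
    seed: int = 0


@dataclass
class RunConfig:
    spacing_mm: float = 0.05
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    enhance: EnhanceConfig = field(default_factory=EnhanceConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def build(dc_type, payload, path):
            known = {f.name: f for f in fields(dc_type)}
            unknown = set(payload) - set(known)
            if unknown:
                raise ValueError(
                    f"unknown config key(s) at {path or 'top level'}: {sorted(unknown)}"
                )
            kwargs = {}
            for name, value in payload.items():
                f = known[name]
                if isinstance(value, dict):
                    sub_type = type(f.default_factory())
                    kwargs[name] = build(sub_type, value, f"{path}{name}.")
                else:
                    kwargs[name] = value
            return dc_type(**kwargs)

        return build(cls, data or {}, "")


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file, or return defaults when ``path`` is None."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.from_dict(data or {})
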