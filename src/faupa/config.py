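"""Run configuration with the study's default constants.

Defaults reproduce the acquisition and analysis constants of the design
this package models: TR 2.5 s, bandpass 0.009-0.08 Hz, 4.0-mm FWHM
smoothing, assignment threshold R 0.8, activation-map threshold R 0.45.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .detect import DetectionParams


@dataclass
class PreprocessConfig:
    fwhm_mm: float = 4.0
    f_lo_hz: float = 0.009
    f_hi_hz: float = 0.08
    voxel_size_mm: float = 3.5
    mask_fraction: float = 0.3


@dataclass
class AssociationConfig:
    r_threshold: float = 0.8
    validation_r: float = 0.8
    map_threshold: float = 0.45
    multi_assign: bool = False


@dataclass
class DynamicsConfig:
    lag_trs: int = 0
    tail: str = "one"
    fisher_z: bool = False
    p_convention: str = "t"


@dataclass
class RunConfig:
    tr_s: float = 2.5
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    association: AssociationConfig = field(default_factory=AssociationConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    seed: int = 0
    verbose: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (
            ("preprocess", PreprocessConfig),
            ("detection", DetectionParams),
            ("association", AssociationConfig),
            ("dynamics", DynamicsConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
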