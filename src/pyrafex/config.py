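"""Pipeline configuration: one flat, YAML-serializable bundle of tunables.

Precedence when running from the CLI is flags > config file > defaults.
Every random behavior in a run is traced to a named seed stored here.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .classify import CvPlan, SvmConfig
from .nca import NcaConfig
from .pyramid import PyramidConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    pyramid: PyramidConfig = field(default_factory=PyramidConfig)
    backbone: str = "stub"  # "stub" or a torchvision model id
    backbone_seed: int = 0
    backbone_dim: int = 1000
    backbone_layer: str = "classifier"
    nca: NcaConfig = field(default_factory=NcaConfig)
    k_select: int = 1000
    svm: SvmConfig = field(default_factory=SvmConfig)
    cv: CvPlan = field(default_factory=CvPlan)
    dataset_dir: str | None = None
    output_dir: str = "pyrafex_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pyramid"]["patch_sides"] = list(self.pyramid.patch_sides)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sub = {
            "pyramid": PyramidConfig,
            "nca": NcaConfig,
            "svm": SvmConfig,
            "cv": CvPlan,
        }
        kwargs = {}
        for key, typ in sub.items():
            if key in data:
                raw = data.pop(key)
                if isinstance(raw, dict):
                    if key == "pyramid" and "patch_sides" in raw:
                        raw = {**raw, "patch_sides": tuple(raw["patch_sides"])}
                    raw = typ(**raw)
                kwargs[key] = raw
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
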