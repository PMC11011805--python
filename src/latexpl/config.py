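"""Run configuration: one YAML file covering every pipeline stage.

CLI flags override file values; each command writes the fully resolved
configuration next to its artifacts for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .aae import AAEConfig
from .explanation import ExplainConfig
from .neighborhood import GASettings


@dataclass
class DataConfig:
    n_per_class: int = 200
    n_classes: int = 3
    resolution: int = 28


@dataclass
class MetricConfig:
    step_frac: float = 0.01
    baseline: str = "mean"


@dataclass
class RunConfig:
    """Everything a pipeline run needs, round-trippable through YAML."""

    seed: int = 0
    out_dir: str = "runs"
    data: DataConfig = field(default_factory=DataConfig)
    aae: AAEConfig = field(default_factory=AAEConfig)
    explain: ExplainConfig = field(default_factory=ExplainConfig)
    metric: MetricConfig = field(default_factory=MetricConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if not isinstance(d, dict):
            raise ValueError("config root must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            val = d[f.name]
            if f.name == "data":
                kw[f.name] = DataConfig(**val)
            elif f.name == "aae":
                for key in ("stage_resolutions", "disc_widths",
                            "epochs_per_stage"):
                    if isinstance(val.get(key), list):
                        val[key] = tuple(val[key])
                kw[f.name] = AAEConfig(**val)
            elif f.name == "explain":
                ga = val.pop("ga", None)
                ec = ExplainConfig(**val)
                if ga:
                    ec.ga = GASettings(**ga)
                kw[f.name] = ec
            elif f.name == "metric":
                kw[f.name] = MetricConfig(**val)
            else:
                kw[f.name] = val
        return cls(**kw)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as e:
            raise ValueError(f"malformed config file: {e}") from e
        return cls.from_dict(raw or {})
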