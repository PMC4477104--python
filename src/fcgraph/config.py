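"""Pipeline configuration: every tunable setting in one serialisable object.

Defaults reproduce the analysis settings this pipeline models: band-pass
0.0-0.08 Hz, partial correlation with automatic shrinkage, sparsity grid
step 0.01 (candidates spanning 0.05-0.50, estimability criteria sigma > 1.1
and mean degree > 2 ln N), 10,000 permutations, FDR q = 0.05, NBS primary
threshold T = 1.6.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "BandConfig", "EstimatorConfig", "GridConfig",
           "NullConfig", "InferenceConfig", "NbsConfig", "demo_config"]


@dataclass
class BandConfig:
    low_hz: float = 0.0
    high_hz: float = 0.08


@dataclass
class EstimatorConfig:
    method: str = "partial"          # "partial" | "pearson"
    shrinkage: str | float = "auto"  # Ledoit-Wolf intensity


@dataclass
class GridConfig:
    mode: str = "auto"               # "auto" (estimability criteria) | "fixed"
    s_min: float = 0.05              # candidate range for auto / range for fixed
    s_max: float = 0.50
    step: float = 0.01
    sigma_floor: float = 1.1
    degree_log_base: float = 2.718281828459045
    n_random: int = 10               # null networks per sigma evaluation (auto)


@dataclass
class NullConfig:
    n_random: int = 100              # null networks for gamma/lambda/sigma
    n_swaps_per_edge: int = 10


@dataclass
class InferenceConfig:
    n_perm: int = 10_000
    q: float = 0.05
    alpha: float = 0.05


@dataclass
class NbsConfig:
    t_threshold: float = 1.6
    n_perm: int = 10_000
    sided: str = "two"
    scope: str = "altered"           # "altered" (two-stage) | "whole"


@dataclass
class PipelineConfig:
    band: BandConfig = field(default_factory=BandConfig)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    nulls: NullConfig = field(default_factory=NullConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    nbs: NbsConfig = field(default_factory=NbsConfig)
    clustering_variant: str = "onnela"
    tr_seconds: float = 2.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = dict(d)
        for name, sub in [("band", BandConfig), ("estimator", EstimatorConfig),
                          ("grid", GridConfig), ("nulls", NullConfig),
                          ("inference", InferenceConfig), ("nbs", NbsConfig)]:
            if name in kw and isinstance(kw[name], dict):
                kw[name] = sub(**kw[name])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def set_override(self, key: str, value: str) -> None:
        """Apply a dotted ``section.field=value`` override (CLI --set)."""
        parts = key.split(".")
        target = self
        for p in parts[:-1]:
            target = getattr(target, p)
        current = getattr(target, parts[-1])
        if isinstance(current, bool):
            value = value.lower() in ("1", "true", "yes")
        elif isinstance(current, int) and not isinstance(current, bool):
            value = int(value)
        elif isinstance(current, float):
            value = float(value)
        setattr(target, parts[-1], value)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def demo_config(seed: int = 0) -> PipelineConfig:
    """Small, fast settings for the end-to-end demo (20 regions, 8/group).

    The demo uses a fixed sparsity grid: the estimability criteria that
    determine the grid automatically are calibrated for ~90-region networks
    (the degree bound 2 ln N forces very dense networks at N = 20, where
    sigma cannot exceed its floor).
    """
    cfg = PipelineConfig(seed=seed)
    cfg.grid = GridConfig(mode="fixed", s_min=0.20, s_max=0.44, step=0.04)
    cfg.nulls = NullConfig(n_random=8)
    cfg.inference = InferenceConfig(n_perm=200)
    cfg.nbs = NbsConfig(n_perm=200)
    return cfg
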