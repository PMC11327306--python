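"""Structured run configuration shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .exceptions import ConfigError

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Thresholds and per-dataset settings for a burden-scan run.

    ``gc_intercepts`` maps dataset label to its LD-score-regression
    intercept (the genomic-control divisor for the LRT chi-squared);
    datasets not listed default to 1.0 (no adjustment).
    """

    maf_threshold: float = 0.001
    sparse_threshold: int = 10
    alpha: float = 0.05
    gc_intercepts: dict[str, float] = field(default_factory=dict)
    covariate_cols: list[str] = field(default_factory=list)
    seed: Optional[int] = None

    def validate(self) -> None:
        if not (0 < self.maf_threshold <= 0.5):
            raise ConfigError("maf_threshold", "must be in (0, 0.5]")
        if self.sparse_threshold < 0:
            raise ConfigError("sparse_threshold", "must be >= 0")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha", "must be in (0, 1)")
        for ds, lam in self.gc_intercepts.items():
            if lam <= 0:
                raise ConfigError("gc_intercepts", f"{ds}: intercept must be > 0")

    def intercept_for(self, dataset: str) -> float:
        return self.gc_intercepts.get(dataset, 1.0)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    for key in raw:
        if key not in known:
            raise ConfigError(key, "unknown configuration key")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg
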