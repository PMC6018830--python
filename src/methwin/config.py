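"""Pipeline configuration: every threshold used by the analysis stages.

All thresholds are plain attributes of :class:`PipelineConfig`; the defaults
encode the standard analysis settings (coverage >= 5 per cytosine, binomial
P <= 1e-4 for mC calls, 100-bp windows on a 50-bp grid, >= 5 cytosines and
>= 25 percent-point difference with q <= 0.01 for DMRs, 2-kb flanks split
into 10 bins, |fold change| >= 2 at P <= 0.05 for differential expression,
24-nt small-RNA loci).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration value violates its invariant."""


@dataclass
class PipelineConfig:
    # mC calling
    min_coverage: int = 5
    mc_alpha: float = 1e-4
    nonconversion_rate: float = 0.005
    # DMR calling
    window_size: int = 100
    window_step: int = 50
    min_cytosines_per_window: int = 5
    min_meth_diff: float = 25.0
    max_qvalue: float = 0.01
    # metagene profile / gene association geometry
    flank_size: int = 2000
    n_bins: int = 10
    # differential expression thresholds (fold change is a signed linear ratio)
    de_min_fold_change: float = 2.0
    de_max_pvalue: float = 0.05
    # small RNA loci
    smrna_length: int = 24
    # global RNG seed
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            "min_coverage",
            "window_size",
            "window_step",
            "min_cytosines_per_window",
            "min_meth_diff",
            "flank_size",
            "n_bins",
            "de_min_fold_change",
            "smrna_length",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive, got {getattr(self, name)!r}")
        if self.window_step > self.window_size:
            raise ConfigError(
                f"window_step ({self.window_step}) must not exceed window_size ({self.window_size})"
            )
        for name in ("mc_alpha", "max_qvalue", "de_max_pvalue"):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise ConfigError(f"{name} must lie in (0, 1), got {value!r}")
        if not (0.0 <= self.nonconversion_rate < 1.0):
            raise ConfigError(
                f"nonconversion_rate must lie in [0, 1), got {self.nonconversion_rate!r}"
            )

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
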