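"""Pipeline configuration: every scalar threshold used by the analysis.

Defaults mirror the validated study design: log2 analysis scale, a 75%-quantile
low-reactivity pre-filter at log2 MFI 10, screening at alpha 0.05 with
fold-change >= 1.5 / SAM d >= 2 / quantile span >= 1, control-anchored
binarization at the 98% healthy-control quantile (at most 2% positive controls),
and the |coefficient| >= 0.45 effect-size filter for clinical associations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    prefilter_quantile: float = 0.75
    prefilter_threshold: float = 10.0  # log2 MFI
    screen_alpha: float = 0.05
    fold_change_min: float = 1.5
    d_score_min: float = 2.0
    span_min: float = 1.0  # log2 units
    cutoff_quantile: float = 0.98
    max_hc_positivity: float = 0.02
    min_spec_hc: float = 0.95
    max_panel_size: int = 5
    coef_min: float = 0.45
    assoc_alpha: float = 0.05
    min_complete_cases: int = 10
    n_permutations: int = 1000  # Monte-Carlo fallback for SAM permutation p
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prefilter_quantile", "cutoff_quantile", "max_hc_positivity",
                     "screen_alpha", "min_spec_hc", "assoc_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("fold_change_min", "d_score_min", "span_min", "coef_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.max_panel_size < 1:
            raise ValueError("max_panel_size must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
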