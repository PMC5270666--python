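"""Run configuration: YAML-backed, validated, with analysis defaults.

All decision thresholds of the analysis are surfaced here: the Bonferroni
gate (0.001), the skewness trigger for the log transform (1.0), the outlier
limit (3.0 SD) and the factor-determinacy acceptance floor (0.80).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    seed: int = 0
    estimator: str = "ml"              # "ml" | "fiml" (delta model)
    gate_alpha: float = 1e-3           # Bonferroni-corrected gate
    skew_threshold: float = 1.0        # |skewness| that triggers the log
    outlier_sd: float = 3.0            # single-pass deletion limit
    determinacy_floor: float = 0.80    # acceptance floor for rho(delta)
    chisq_divisor: str = "n-1"
    cohort_csv: str | None = None      # when None, a cohort is simulated
    truth_json: str | None = None
    splithalf: bool = True
    splithalf_max: int = 5             # class-1 models taken to split-half
    simulate: dict = field(default_factory=dict)  # SynthConfig overrides

    def __post_init__(self):
        if self.estimator not in {"ml", "fiml"}:
            raise ConfigError(f"estimator must be ml|fiml, "
                              f"got {self.estimator!r}")
        if not 0 < self.gate_alpha < 1:
            raise ConfigError("gate_alpha must lie in (0, 1)")
        if self.chisq_divisor not in {"n-1", "n"}:
            raise ConfigError("chisq_divisor must be 'n-1' or 'n'")
        from .synthetic import SynthConfig
        known = {f.name for f in dataclasses.fields(SynthConfig)}
        bad = set(self.simulate) - known
        if bad:
            raise ConfigError(f"unknown simulate key(s): {sorted(bad)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> AnalysisConfig:
    """Load and validate a YAML run configuration; unknown keys error."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    bad = set(doc) - known
    if bad:
        raise ConfigError(f"unknown configuration key(s): {sorted(bad)}")
    return AnalysisConfig(**doc)
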