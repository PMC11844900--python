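"""Analysis configuration (YAML-loadable).

Defaults mirror the published protocol: group coefficients of variation of 5%
(CAD) and 4% (CON), ROPE at 20% of the group baseline SD, 89% HDI from 1000
posterior draws, and the >99% / <1% in-ROPE decision thresholds. Every knob
the protocol leaves ambiguous (CV source, delta pooling, ROPE bounds) is
explicit here so sensitivity analyses need no code changes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator


class AnalysisConfig(BaseModel):
    #: mapping from file column names onto canonical ones, applied on read
    column_map: dict[str, str] = Field(default_factory=dict)
    #: where the technical-error CV comes from: the published group values, or
    #: per-participant estimates from duplicate replicate measurements
    cv_source: Literal["group", "individual"] = "group"
    group_cvs: dict[str, float] = Field(default_factory=lambda: {"CAD": 0.05, "CON": 0.04})
    #: ROPE half-width as a fraction of the group baseline SD
    rope_fraction: float = Field(default=0.2, gt=0)
    #: direct half-width overrides keyed "<outcome>:<group>", e.g. "csbp:CAD"
    rope_overrides: dict[str, float] = Field(default_factory=dict)
    hdi_mass: float = Field(default=0.89, gt=0, lt=1)
    n_draws: int = Field(default=1000, ge=100)
    upper_threshold: float = Field(default=0.99, gt=0, le=1)
    lower_threshold: float = Field(default=0.01, ge=0, lt=1)
    #: post-exercise timepoints pooled (averaged) into the individual delta
    delta_timepoints: list[str] = Field(default_factory=lambda: ["P15", "P30"])
    #: "hdi": % of HDI draws inside ROPE; "full": % of all draws inside ROPE
    pct_scope: Literal["hdi", "full"] = "hdi"
    #: aerobic TRIMP weights per heart-rate zone
    zone_weights: dict[str, float] = Field(
        default_factory=lambda: {"BELOW_VT1": 1.0, "AT_VT1": 2.0, "AT_VT2": 3.0}
    )

    @model_validator(mode="after")
    def _thresholds_ordered(self) -> "AnalysisConfig":
        if not self.lower_threshold < self.upper_threshold:
            raise ValueError("lower_threshold must be below upper_threshold")
        return self


def load_config(path: Optional[str | Path]) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from YAML; ``None`` gives the defaults."""
    if path is None:
        return AnalysisConfig()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return AnalysisConfig(**raw)
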