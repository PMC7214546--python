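"""Run configuration shared by every pipeline stage."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

#: Centre labels. A and B are the cost-observed centres (their finance
#: departments supplied per-episode costs); C is the cost-missing centre
#: whose costs are predicted from the fitted model.
COST_OBSERVED_CENTRES = ("A", "B")
COST_MISSING_CENTRE = "C"
CENTRES = ("A", "B", "C")

GENDERS = ("male", "female")
METHODS = ("poisoning", "injury", "both")


class PipelineConfig(BaseModel):
    """All tunable constants of the estimation pipeline.

    Money is GBP at 2013/14 prices unless stated otherwise.
    """

    #: Unit cost of a psychosocial assessment added to episodes whose
    #: recorded cost excludes it ("younger than 18" semantics for the
    #: child rate).
    assessment_unit_cost_child: float = Field(default=392.0, ge=0)
    assessment_unit_cost_adult: float = Field(default=228.0, ge=0)
    child_age_threshold: int = Field(default=18, ge=0)

    #: Monte-Carlo settings for the cost-uncertainty interval.
    mc_iterations: int = Field(default=10_000, gt=0)
    ci_level: float = Field(default=0.95, gt=0, lt=1)

    #: Rurality sensitivity: proportional reduction of presentations in
    #: fully rural populations relative to urban, by gender.
    rural_reduction_male: float = Field(default=0.31, ge=0, le=1)
    rural_reduction_female: float = Field(default=0.26, ge=0, le=1)
    #: If True, an area counts as rural iff rural_fraction > 0.5 (binary
    #: classification); otherwise the rural fraction linearly interpolates
    #: between the urban and fully-rural endpoints.
    rurality_binary_mode: bool = False

    #: Hospital & Community Health Services index, 2013/14 -> 2017.
    inflation_factor_2017: float = Field(default=1.04062, gt=0)

    rng_seed: int = 0

    #: Ages above this are pooled into one open-ended band for rates and
    #: cost cells (single-year cells are empty at the oldest ages).
    age_cap: int = Field(default=90, gt=0)

    #: Mean-cost cells with fewer contributing episodes than this are
    #: pooled into their enclosing 10-year age band.
    cost_cell_min_n: int = Field(default=5, gt=0)

    #: If True, the mean-cost table uses model predictions for every centre
    #: rather than observed costs for the cost-observed centres plus
    #: predictions for the cost-missing one.
    predict_all_centres: bool = False

    #: Age covariate handling in the cost model: continuous per-year
    #: (default) or 10-year band factors.
    age_as_bands: bool = False

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.child_age_threshold > self.age_cap:
            raise ValueError("child_age_threshold must not exceed age_cap")
        return self

    def config_hash(self) -> str:
        """Stable digest of the configuration (for run manifests)."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)
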