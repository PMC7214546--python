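"""Univariate sensitivity recalibrations of the incidence estimates.

Two multiplicative adjustment-factor families are supported, each applied
on its own (the analyses are univariate):

* suicide-rate calibration — an area's factor per gender is its
  age-standardised suicide rate divided by the average rate of the three
  sentinel centre areas;
* rurality calibration — presentations are reduced in proportion to the
  rural population share, reaching 31% (male) / 26% (female) below the
  urban level in a fully rural area.
"""

from __future__ import annotations

import pandas as pd

from selfharm_burden.config import GENDERS, PipelineConfig


def suicide_adjustment_factors(
    suicide_rates: pd.DataFrame,
    centre_areas: list[str],
) -> pd.DataFrame:
    """factor(area, gender) = ASR(area, gender) / mean centre ASR(gender)."""
    centre = suicide_rates[suicide_rates["area_id"].isin(centre_areas)]
    if set(centre["area_id"]) != set(centre_areas):
        missing = set(centre_areas) - set(centre["area_id"])
        raise ValueError(f"centre areas missing from suicide rates: {missing}")
    centre_avg = centre.groupby("gender")["asr"].mean()
    if (centre_avg <= 0).any():
        raise ValueError("centre-average suicide rate must be positive")
    out = suicide_rates.copy()
    out["factor"] = out["asr"] / out["gender"].map(centre_avg)
    out["kind"] = "suicide"
    return out[["area_id", "gender", "factor", "kind"]]


def rurality_adjustment_factors(
    rurality: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Gendered downscaling by rural population share.

    Fraction-weighted by default: factor = 1 − rural_fraction × reduction,
    interpolating between the urban (1.0) and fully-rural endpoints.  In
    binary mode an area with rural_fraction > 0.5 gets the full reduction
    and any other area none.
    """
    config = config or PipelineConfig()
    reductions = {"male": config.rural_reduction_male,
                  "female": config.rural_reduction_female}
    rows = []
    for row in rurality.itertuples(index=False):
        if config.rurality_binary_mode:
            weight = 1.0 if row.rural_fraction > 0.5 else 0.0
        else:
            weight = row.rural_fraction
        for gender in GENDERS:
            rows.append({
                "area_id": row.area_id,
                "gender": gender,
                "factor": 1.0 - weight * reductions[gender],
                "kind": "rurality",
            })
    return pd.DataFrame(rows)


def apply_adjustment(
    incidence: pd.DataFrame,
    factors: pd.DataFrame,
) -> pd.DataFrame:
    """Multiply every incidence cell by its area-and-gender factor."""
    merged = incidence.merge(factors[["area_id", "gender", "factor"]],
                             on=["area_id", "gender"], how="left")
    missing = merged["factor"].isna()
    if missing.any():
        cells = (merged.loc[missing, ["area_id", "gender"]]
                 .drop_duplicates().to_dict("records"))
        raise ValueError(f"no adjustment factor for: {cells}")
    out = merged.copy()
    out["expected_presentations"] = (out["expected_presentations"]
                                     * out["factor"])
    return out.drop(columns="factor")
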