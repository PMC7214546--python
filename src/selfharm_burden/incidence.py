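"""Sentinel rate estimation and small-area extrapolation.

Presentation rates per person-year are estimated by dividing episode
counts in the sentinel catchment by its population, for each single year
of age (capped band at the top) and gender; multiplying these rates into
any other area's population pyramid gives its expected presentation
counts.  Events are episodes, not persons: national patient counts are
derived afterwards by scaling with the sentinel patients-to-episodes
ratio per gender.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATCHMENT_AREA_ID = "CATCHMENT"


class CellCoverageError(ValueError):
    """An episode falls in an (age, gender) cell absent from the catchment."""


def estimate_rates(
    episodes: pd.DataFrame,
    catchment_pop: pd.DataFrame,
    age_cap: int = 90,
) -> pd.DataFrame:
    """Presentation rate per person-year by (age, gender).

    ``catchment_pop`` holds the sentinel population (one row per age and
    gender; if several areas are passed they are summed).  Returns one row
    per catchment cell with columns [age, gender, rate, n_events, n_pop,
    zero_pop_flag]; cells with no population get rate 0 and the flag.
    """
    pop = (
        catchment_pop.assign(age=lambda d: d["age"].clip(upper=age_cap))
        .groupby(["age", "gender"], as_index=False)["population"].sum()
    )
    ep = episodes.copy()
    ep["age"] = ep["age"].clip(upper=age_cap)
    counts = (
        ep.groupby(["age", "gender"]).size().rename("n_events").reset_index()
    )

    merged = pop.merge(counts, on=["age", "gender"], how="outer",
                       indicator=True)
    orphan = merged["_merge"] == "right_only"
    if orphan.any():
        cells = merged.loc[orphan, ["age", "gender"]].to_dict("records")
        raise CellCoverageError(
            f"episodes outside catchment population cells: {cells}"
        )
    merged = merged.drop(columns="_merge").fillna({"n_events": 0})
    merged["n_events"] = merged["n_events"].astype(int)
    merged["n_pop"] = merged["population"]
    merged["zero_pop_flag"] = merged["n_pop"] <= 0
    merged["rate"] = np.where(
        merged["zero_pop_flag"], 0.0, merged["n_events"] / merged["n_pop"]
    )
    if merged.loc[merged["zero_pop_flag"], "n_events"].sum() > 0:
        raise CellCoverageError("episodes in a zero-population catchment cell")
    return merged[["age", "gender", "rate", "n_events", "n_pop",
                   "zero_pop_flag"]].sort_values(
        ["gender", "age"]).reset_index(drop=True)


def extrapolate_incidence(
    rates: pd.DataFrame,
    area_pop: pd.DataFrame,
    age_cap: int = 90,
) -> pd.DataFrame:
    """Expected presentations per (area, age, gender) cell.

    Populated cells with no matching rate row receive rate 0 with a
    ``missing_rate_flag`` (and a log entry) rather than borrowing a
    neighbouring rate.  Counts are kept fractional.
    """
    pop = (
        area_pop.assign(age=lambda d: d["age"].clip(upper=age_cap))
        .groupby(["area_id", "age", "gender"], as_index=False)
        ["population"].sum()
    )
    out = pop.merge(rates[["age", "gender", "rate"]], on=["age", "gender"],
                    how="left")
    out["missing_rate_flag"] = out["rate"].isna() & (out["population"] > 0)
    n_flagged = int(out["missing_rate_flag"].sum())
    if n_flagged:
        logger.warning(
            "%d populated area cells have no sentinel rate; set to 0",
            n_flagged,
        )
    out["rate"] = out["rate"].fillna(0.0)
    out["expected_presentations"] = out["rate"] * out["population"]
    return out[["area_id", "age", "gender", "expected_presentations",
                "population", "missing_rate_flag"]]


def national_totals(
    incidence: pd.DataFrame,
    sentinel_episodes: pd.DataFrame | None = None,
    band_width: int = 10,
) -> dict:
    """Roll the incidence table up to totals.

    Returns a dict with the overall episode total, totals by gender, a
    by-age-band table, and — when the sentinel episode table is supplied —
    estimated distinct-patient totals obtained by scaling episode totals
    with the sentinel patients-to-episodes ratio per gender (the declared
    approximation for patient counts).
    """
    by_gender = (
        incidence.groupby("gender")["expected_presentations"].sum().to_dict()
    )
    inc = incidence.assign(band=(incidence["age"] // band_width) * band_width)
    by_band = (
        inc.groupby(["band", "gender"], as_index=False)
        ["expected_presentations"].sum()
    )
    result = {
        "episodes_total": float(incidence["expected_presentations"].sum()),
        "episodes_by_gender": {g: float(v) for g, v in by_gender.items()},
        "by_age_band": by_band,
    }
    if sentinel_episodes is not None and len(sentinel_episodes):
        ratio = (
            sentinel_episodes.groupby("gender")["patient_id"]
            .agg(lambda s: s.nunique() / len(s))
        )
        patients_by_gender = {
            g: float(by_gender.get(g, 0.0) * ratio.get(g, np.nan))
            for g in by_gender
        }
        result["patients_by_gender"] = patients_by_gender
        result["patients_total"] = float(
            np.nansum(list(patients_by_gender.values()))
        )
        result["sentinel_patient_episode_ratio"] = {
            g: float(r) for g, r in ratio.items()
        }
    return result
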