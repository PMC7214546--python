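"""Tabular input/output with validation.

All artefacts are UTF-8 comma-separated text with a header row.  Readers
validate invariants and either reject offending rows with row-indexed
diagnostics (episode table) or raise (geography tables, where a malformed
key structure makes the whole table unusable).

Schemas
-------
episodes.csv      episode_id, patient_id, centre, age, gender, method,
                  admitted, assessed, observed_cost, assessment_cost_included
population.csv    area_id, age, gender, population
mff.csv           area_id, mff
suicide_asr.csv   area_id, gender, asr
rurality.csv      area_id, rural_fraction
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from selfharm_burden.config import (
    CENTRES,
    COST_OBSERVED_CENTRES,
    GENDERS,
    METHODS,
    PipelineConfig,
)


class SchemaError(ValueError):
    """A table is structurally unusable (missing columns, duplicate keys)."""


@dataclass(frozen=True)
class Diagnostic:
    """One row-level validation finding."""

    row: int
    field: str
    message: str
    level: str = "error"  # "error" rows are rejected; "warning" rows kept


EPISODE_COLUMNS = [
    "episode_id",
    "patient_id",
    "centre",
    "age",
    "gender",
    "method",
    "admitted",
    "assessed",
    "observed_cost",
    "assessment_cost_included",
]

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False,
}


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing mandatory column(s) {missing}")


def _coerce_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    return series.astype(str).str.strip().str.lower().map(_BOOL_MAP)


def read_episode_table(
    path: str | Path,
) -> tuple[pd.DataFrame, list[Diagnostic]]:
    """Read and validate an episode table.

    Rows violating a record invariant are dropped and reported; rows with
    a recorded cost at the cost-missing centre are kept but flagged with a
    warning diagnostic (the value is retained).

    Returns the validated frame (0-based positional index of the source
    row preserved in the diagnostics) and the list of diagnostics.
    """
    df = pd.read_csv(path, dtype={"episode_id": str, "patient_id": str})
    # observed_cost and assessment_cost_included may be absent when the
    # file only covers the cost-missing centre
    if "observed_cost" not in df.columns:
        df["observed_cost"] = np.nan
    if "assessment_cost_included" not in df.columns:
        df["assessment_cost_included"] = False
    _require_columns(df, EPISODE_COLUMNS, "episodes")
    df = df[EPISODE_COLUMNS].copy()
    return validate_episodes(df)


def validate_episodes(
    df: pd.DataFrame,
) -> tuple[pd.DataFrame, list[Diagnostic]]:
    """Apply episode-record invariants to an in-memory frame."""
    df = df.copy().reset_index(drop=True)
    diagnostics: list[Diagnostic] = []
    bad = pd.Series(False, index=df.index)

    def flag(mask: pd.Series, field: str, message: str) -> None:
        nonlocal bad
        for row in df.index[mask & ~bad]:
            diagnostics.append(Diagnostic(int(row), field, message))
        bad |= mask

    for col in ("admitted", "assessed", "assessment_cost_included"):
        df[col] = _coerce_bool(df[col])
        flag(df[col].isna(), col, "not a recognised boolean")
        df[col] = df[col].fillna(False).astype(bool)

    age = pd.to_numeric(df["age"], errors="coerce")
    flag(age.isna() | (age < 0) | (age > 120) | (age != age.round()),
         "age", "age must be an integer in [0, 120]")
    df["age"] = age.fillna(-1).astype(int)

    flag(~df["centre"].isin(CENTRES), "centre",
         f"centre must be one of {CENTRES}")
    flag(~df["gender"].isin(GENDERS), "gender",
         f"gender must be one of {GENDERS}")
    flag(~df["method"].isin(METHODS), "method",
         f"method must be one of {METHODS}")

    cost = pd.to_numeric(df["observed_cost"], errors="coerce")
    df["observed_cost"] = cost
    observed_centre = df["centre"].isin(COST_OBSERVED_CENTRES)
    flag(observed_centre & cost.isna(), "observed_cost",
         "cost missing for cost-observed centre")
    flag(cost.notna() & (cost < 0), "observed_cost",
         "observed_cost must be nonnegative")
    # cost recorded for the cost-missing centre: keep, but flag
    for row in df.index[~observed_centre & cost.notna() & ~bad]:
        diagnostics.append(Diagnostic(
            int(row), "observed_cost",
            "cost recorded for cost-missing centre (retained)", "warning"))

    dup = df["episode_id"].duplicated(keep="first")
    flag(dup, "episode_id", "duplicate episode_id")

    # single-catchment assumption: a patient attends one centre
    first_centre = df.groupby("patient_id")["centre"].transform("first")
    flag(df["centre"].ne(first_centre) & ~bad, "patient_id",
         "patient appears at more than one centre")

    return df.loc[~bad].reset_index(drop=True), diagnostics


def _read_keyed(
    path: str | Path,
    columns: list[str],
    keys: list[str],
    table: str,
) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, columns, table)
    df = df[columns].copy()
    dup = df.duplicated(subset=keys, keep=False)
    if dup.any():
        dupes = df.loc[dup, keys].drop_duplicates().to_dict("records")
        raise SchemaError(f"{table}: duplicate key rows {dupes}")
    return df


def read_population_table(path: str | Path) -> pd.DataFrame:
    df = _read_keyed(path, ["area_id", "age", "gender", "population"],
                     ["area_id", "age", "gender"], "population")
    if not df["gender"].isin(GENDERS).all():
        raise SchemaError("population: unknown gender value")
    if (df["population"] < 0).any():
        raise SchemaError("population: negative population count")
    df["age"] = df["age"].astype(int)
    df["population"] = df["population"].astype(float)
    return df


def read_mff(path: str | Path) -> pd.DataFrame:
    df = _read_keyed(path, ["area_id", "mff"], ["area_id"], "mff")
    if (df["mff"] <= 0).any():
        raise SchemaError("mff: price index must be positive")
    return df


def read_suicide_rates(path: str | Path) -> pd.DataFrame:
    df = _read_keyed(path, ["area_id", "gender", "asr"],
                     ["area_id", "gender"], "suicide_asr")
    if not df["gender"].isin(GENDERS).all():
        raise SchemaError("suicide_asr: unknown gender value")
    if (df["asr"] < 0).any():
        raise SchemaError("suicide_asr: negative age-standardised rate")
    return df


def read_rurality(path: str | Path) -> pd.DataFrame:
    df = _read_keyed(path, ["area_id", "rural_fraction"], ["area_id"],
                     "rurality")
    if ((df["rural_fraction"] < 0) | (df["rural_fraction"] > 1)).any():
        raise SchemaError("rurality: rural_fraction must lie in [0, 1]")
    return df


def write_outputs(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Write tables as CSV with deterministic order, plus a JSON manifest.

    Rows are sorted on all columns and columns keep their frame order, so
    identical inputs yield byte-identical files.  The manifest records per
    file the row count and content digest, the configuration hash and the
    seed; it is returned and also written as ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, dict] = {}
    for name in sorted(tables):
        df = tables[name]
        if len(df):
            df = df.sort_values(list(df.columns), kind="mergesort")
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        files[name] = {"path": path.name, "rows": int(len(df)),
                       "sha256": digest}
    manifest = {
        "files": files,
        "config_hash": config.config_hash() if config else None,
        "seed": seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
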