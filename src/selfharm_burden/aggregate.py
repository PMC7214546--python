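"""Area cost totals and Monte-Carlo uncertainty propagation.

Total cost per area is the sum over (age, gender) cells of expected
presentations times the mean cost per presentation.  Uncertainty from the
cost-model transfer is propagated by drawing the coefficient vector from a
multivariate normal with the cluster-robust covariance, recomputing the
predicted costs, the pooled mean-cost table and the totals for each draw,
and reporting percentile intervals.  Only coefficient uncertainty varies
across draws: incidence and directly observed costs are held fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from selfharm_burden.config import COST_MISSING_CENTRE, PipelineConfig
from selfharm_burden.costing import (
    CENTRE_AREA_IDS,
    CostModel,
    design_matrix,
    pooling_assignments,
)


def aggregate_costs(
    incidence: pd.DataFrame,
    mean_costs: pd.DataFrame,
    population: pd.DataFrame,
) -> pd.DataFrame:
    """Per-area totals: cost, presentations, and per-1,000 figures.

    ``mean_costs`` must cover every (age, gender) cell of the incidence
    table.  Returns one row per area plus per-gender breakdown columns;
    a national rollup is just the column sum over any set of areas.
    """
    merged = incidence.merge(mean_costs[["age", "gender", "mean_cost"]],
                             on=["age", "gender"], how="left")
    missing = merged["mean_cost"].isna() & (
        merged["expected_presentations"] > 0)
    if missing.any():
        cells = merged.loc[missing, ["age", "gender"]].drop_duplicates()
        raise ValueError(
            f"mean cost undefined for incidence cells: "
            f"{cells.to_dict('records')}"
        )
    merged["cell_cost"] = (merged["expected_presentations"]
                           * merged["mean_cost"].fillna(0.0))

    pop_totals = (population.groupby("area_id")["population"].sum())
    rows = []
    for area, g in merged.groupby("area_id"):
        if area not in pop_totals.index:
            raise ValueError(f"area {area!r} missing from population table")
        pop = float(pop_totals[area])
        by_gender_cost = g.groupby("gender")["cell_cost"].sum()
        by_gender_pres = g.groupby("gender")["expected_presentations"].sum()
        total_cost = float(g["cell_cost"].sum())
        presentations = float(g["expected_presentations"].sum())
        rows.append({
            "area_id": area,
            "total_cost": total_cost,
            "presentations": presentations,
            "population": pop,
            "cost_per_1000": total_cost / pop * 1000 if pop else np.nan,
            "presentations_per_1000":
                presentations / pop * 1000 if pop else np.nan,
            "cost_male": float(by_gender_cost.get("male", 0.0)),
            "cost_female": float(by_gender_cost.get("female", 0.0)),
            "presentations_male": float(by_gender_pres.get("male", 0.0)),
            "presentations_female": float(by_gender_pres.get("female", 0.0)),
        })
    return pd.DataFrame(rows).sort_values("area_id").reset_index(drop=True)


@dataclass
class UncertaintyResult:
    """Monte-Carlo draws of national and per-area cost totals."""

    national_draws: np.ndarray          # (n_iter,)
    area_draws: pd.DataFrame            # (n_iter, n_areas)
    seed: int
    n_iter: int
    national_point: float
    national_ci: tuple[float, float]
    area_ci: pd.DataFrame               # area_id, ci_low, ci_high


def _psd_sqrt(vcov: np.ndarray) -> np.ndarray:
    """Matrix square root, projecting to the nearest PSD matrix if needed."""
    w, V = np.linalg.eigh((vcov + vcov.T) / 2)
    tol = -1e-10 * max(abs(w).max(), 1.0)
    if w.min() < tol:
        warnings.warn("vcov not positive semi-definite; "
                      "projected to nearest PSD matrix")
    return V @ np.diag(np.sqrt(np.clip(w, 0, None)))


def monte_carlo_intervals(
    model: CostModel,
    episodes: pd.DataFrame,
    incidence: pd.DataFrame,
    population: pd.DataFrame,
    mff: pd.DataFrame | None,
    config: PipelineConfig,
    seed: int,
) -> tuple[UncertaintyResult, pd.DataFrame]:
    """Percentile intervals for cost totals under coefficient uncertainty.

    Per iteration a coefficient vector is drawn from
    N(beta, vcov); predicted episode costs, the pooled mean-cost table and
    all area totals are recomputed.  Observed-cost episodes are held fixed
    across draws (their costs do not depend on the coefficients) unless
    ``config.predict_all_centres`` is set.  Returns the draw container and
    the per-area estimate table augmented with CI columns.

    The recomputation is algebraically collapsed: with fixed pooling
    groups the total is an affine function of the drawn episode
    predictions, so each iteration costs one matrix-vector product.
    """
    rng = np.random.default_rng(seed)
    n_iter = config.mc_iterations
    alpha = (1 - config.ci_level) / 2

    ep = episodes.reset_index(drop=True)
    predicted_mask = (
        np.ones(len(ep), dtype=bool)
        if config.predict_all_centres
        else ep["centre"].eq(COST_MISSING_CENTRE).to_numpy()
    )

    cells = incidence[["age", "gender"]].drop_duplicates()
    cell_groups, keys = pooling_assignments(ep, config, cells)

    # group bookkeeping: each cell averages over one episode pool
    group_key = cell_groups.apply(
        lambda r: (r["level"], r["group_age"], r["gender"]), axis=1)
    unique_groups = sorted(set(group_key))
    gindex = {g: i for i, g in enumerate(unique_groups)}
    n_groups = len(unique_groups)

    ep_levels = {
        "cell": list(zip(keys["age_c"], keys["gender"])),
        "band": list(zip(keys["band"], keys["gender"])),
    }
    member_idx: list[np.ndarray] = []
    for level, age, gender in unique_groups:
        if level == "cell":
            mask = np.array([k == (age, gender) for k in ep_levels["cell"]])
        elif level == "band":
            mask = np.array([k == (age, gender) for k in ep_levels["band"]])
        else:
            mask = (keys["gender"] == gender).to_numpy()
        member_idx.append(np.flatnonzero(mask))
    n_g = np.array([len(ix) for ix in member_idx], dtype=float)
    if (n_g == 0).any():
        raise ValueError("empty pooling group")

    # incidence weight of each group, per area
    inc = incidence.copy()
    inc["age"] = inc["age"].clip(upper=config.age_cap)
    inc = inc.groupby(["area_id", "age", "gender"], as_index=False)[
        "expected_presentations"].sum()
    cg = cell_groups.copy()
    cg["gid"] = [gindex[k] for k in group_key]
    inc = inc.merge(cg[["age", "gender", "gid"]], on=["age", "gender"],
                    how="left")
    if inc["gid"].isna().any():
        raise ValueError("incidence cell without a pooling group")
    areas = sorted(inc["area_id"].unique())
    aindex = {a: i for i, a in enumerate(areas)}
    M = np.zeros((len(areas), n_groups))
    for (a, gid), w in inc.groupby(["area_id", "gid"])[
            "expected_presentations"].sum().items():
        M[aindex[a], int(gid)] += w

    # fixed (observed) and varying (predicted) cost contributions per group
    obs_cost = np.where(predicted_mask, 0.0,
                        ep["observed_cost"].fillna(0.0).to_numpy())
    fixed_group_sum = np.array([obs_cost[ix].sum() for ix in member_idx])

    pred_rows = np.flatnonzero(predicted_mask)
    X_pred = (
        design_matrix(ep.iloc[pred_rows], model.age_as_bands, model.age_cap)
        .reindex(columns=model.beta.index, fill_value=0.0)
        .to_numpy()
    )
    if mff is not None and len(pred_rows):
        lookup = mff.set_index("area_id")["mff"]
        scale = (
            ep.iloc[pred_rows]["centre"]
            .map(lambda c: lookup.get(CENTRE_AREA_IDS.get(c, c), np.nan))
            .to_numpy()
            / model.fit_mff
        )
        if np.isnan(scale).any():
            raise KeyError("MFF missing for a prediction target centre")
    else:
        scale = np.ones(len(pred_rows))

    # membership of predicted episodes in each group
    pred_pos = {r: j for j, r in enumerate(pred_rows)}
    pred_member = [
        np.array([pred_pos[r] for r in ix if r in pred_pos], dtype=int)
        for ix in member_idx
    ]

    beta = model.beta.to_numpy()
    L = _psd_sqrt(model.vcov.to_numpy())
    k = len(beta)

    area_draws = np.empty((n_iter, len(areas)))
    chunk = max(1, min(n_iter, int(2e7 // max(len(pred_rows), 1)) or 1))
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        Z = rng.standard_normal((k, m))
        B = beta[:, None] + L @ Z
        P = np.exp(X_pred @ B) * scale[:, None] if len(pred_rows) else \
            np.zeros((0, m))
        group_sum = np.empty((n_groups, m))
        for gi, ix in enumerate(pred_member):
            group_sum[gi] = (P[ix].sum(axis=0) if len(ix) else 0.0) \
                + fixed_group_sum[gi]
        means = group_sum / n_g[:, None]
        area_draws[done:done + m] = (M @ means).T
        done += m

    national_draws = area_draws.sum(axis=1)

    # point estimate at beta-hat, through the identical algebra
    P0 = np.exp(X_pred @ beta) * scale if len(pred_rows) else np.zeros(0)
    gs0 = np.array([
        (P0[ix].sum() if len(ix) else 0.0) + fixed_group_sum[gi]
        for gi, ix in enumerate(pred_member)
    ])
    area_point = M @ (gs0 / n_g)
    national_point = float(area_point.sum())

    lo = np.quantile(area_draws, alpha, axis=0)
    hi = np.quantile(area_draws, 1 - alpha, axis=0)
    area_ci = pd.DataFrame({
        "area_id": areas,
        "total_cost": area_point,
        "ci_low": lo,
        "ci_high": hi,
    })
    national_ci = (
        float(np.quantile(national_draws, alpha)),
        float(np.quantile(national_draws, 1 - alpha)),
    )
    result = UncertaintyResult(
        national_draws=national_draws,
        area_draws=pd.DataFrame(area_draws, columns=areas),
        seed=seed,
        n_iter=n_iter,
        national_point=national_point,
        national_ci=national_ci,
        area_ci=area_ci,
    )
    return result, area_ci


def inflate_to_year(total: float, factor: float) -> float:
    """Uprate a cost total by a price-inflation factor."""
    if factor <= 0:
        raise ValueError("inflation factor must be positive")
    return total * factor


def as_million(x: float, ndigits: int = 1) -> float:
    """Express a GBP figure in £ million at reporting precision."""
    return round(x / 1e6, ndigits)


def per_suicide_ratios(
    episodes_by_gender: dict[str, float],
    patients_by_gender: dict[str, float],
    suicides_by_gender: dict[str, float],
) -> pd.DataFrame:
    """Self-harm presentations (and patients) per suicide death.

    Strata: each gender plus 'total'.  Rounded ratios are reported to the
    nearest integer; the unrounded values are retained.
    """
    rows = []
    strata = sorted(suicides_by_gender) + ["total"]
    for stratum in strata:
        if stratum == "total":
            deaths = sum(suicides_by_gender.values())
            eps = sum(episodes_by_gender.values())
            pats = sum(patients_by_gender.values())
        else:
            deaths = suicides_by_gender[stratum]
            eps = episodes_by_gender.get(stratum, 0.0)
            pats = patients_by_gender.get(stratum, 0.0)
        if deaths <= 0:
            raise ValueError(f"suicide deaths must be positive ({stratum})")
        for measure, num in (("episodes", eps), ("patients", pats)):
            rows.append({
                "stratum": stratum,
                "measure": measure,
                "ratio_unrounded": num / deaths,
                "ratio": int(round(num / deaths)),
            })
    return pd.DataFrame(rows)
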