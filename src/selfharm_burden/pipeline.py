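"""End-to-end orchestration: inputs -> incidence -> costs -> estimates.

Each stage is a plain function over data frames so it can be re-run from
persisted intermediates; ``run_all`` chains them, writes every artefact
and a reproducibility manifest, and logs cell-count summaries so silent
data loss is visible.
"""

from __future__ import annotations

import hashlib
import logging
import time
from pathlib import Path

import pandas as pd

from selfharm_burden import __version__
from selfharm_burden import io as sio
from selfharm_burden.aggregate import (
    aggregate_costs,
    as_million,
    inflate_to_year,
    monte_carlo_intervals,
    per_suicide_ratios,
)
from selfharm_burden.config import PipelineConfig
from selfharm_burden.costing import (
    CENTRE_AREA_IDS,
    combine_costs,
    compute_mean_cost_table,
    fit_cost_model,
    impute_assessment_costs,
)
from selfharm_burden.incidence import (
    CATCHMENT_AREA_ID,
    estimate_rates,
    extrapolate_incidence,
    national_totals,
)
from selfharm_burden.sensitivity import (
    apply_adjustment,
    rurality_adjustment_factors,
    suicide_adjustment_factors,
)
from selfharm_burden.synth import default_truth, generate_episodes, generate_geography

logger = logging.getLogger(__name__)


def synthetic_deaths_by_gender(
    suicide_rates: pd.DataFrame, population: pd.DataFrame, areas: list[str]
) -> dict[str, float]:
    """Implied suicide deaths: ASR per 100,000 times area population."""
    pop = (
        population[population["area_id"].isin(areas)]
        .groupby(["area_id", "gender"], as_index=False)["population"].sum()
    )
    merged = pop.merge(suicide_rates, on=["area_id", "gender"], how="inner")
    merged["deaths"] = merged["asr"] / 1e5 * merged["population"]
    return merged.groupby("gender")["deaths"].sum().to_dict()


def run_all(
    config: PipelineConfig,
    out_dir: str | Path,
    input_dir: str | Path | None = None,
    synth_preset: str | None = None,
) -> dict:
    """Run the whole pipeline and write all artefacts under ``out_dir``.

    Inputs come either from generated synthetic data (``synth_preset``)
    or from the five CSVs in ``input_dir``.  Returns a dict with every
    intermediate and the run manifest.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    seed = config.rng_seed

    if synth_preset is not None:
        truth = default_truth(synth_preset)
        episodes = generate_episodes(truth, seed)
        population, mff, suicide_asr, rurality = generate_geography(
            truth, seed + 1)
        input_digests = {"synthetic_preset": synth_preset}
    else:
        if input_dir is None:
            raise ValueError("either input_dir or synth_preset is required")
        ind = Path(input_dir)
        paths = {name: ind / f"{name}.csv" for name in
                 ("episodes", "population", "mff", "suicide_asr", "rurality")}
        for name, p in paths.items():
            if not p.exists():
                raise FileNotFoundError(
                    f"stage 'inputs': required file {p} is missing")
        episodes, diags = sio.read_episode_table(paths["episodes"])
        n_err = sum(d.level == "error" for d in diags)
        if n_err:
            logger.warning("inputs: %d episode rows rejected", n_err)
        population = sio.read_population_table(paths["population"])
        mff = sio.read_mff(paths["mff"])
        suicide_asr = sio.read_suicide_rates(paths["suicide_asr"])
        rurality = sio.read_rurality(paths["rurality"])
        input_digests = {
            name: hashlib.sha256(p.read_bytes()).hexdigest()
            for name, p in paths.items()
        }
    logger.info("inputs: %d episodes, %d population rows",
                len(episodes), len(population))
    timings["inputs"] = time.time() - t0

    # --- incidence -------------------------------------------------------
    t = time.time()
    catchment_pop = population[population["area_id"] == CATCHMENT_AREA_ID]
    rates = estimate_rates(episodes, catchment_pop, config.age_cap)
    national_areas = sorted(
        a for a in population["area_id"].unique() if a != CATCHMENT_AREA_ID
    )
    area_pop = population[population["area_id"].isin(national_areas)]
    incidence_table = extrapolate_incidence(rates, area_pop, config.age_cap)
    totals = national_totals(incidence_table, episodes)
    timings["incidence"] = time.time() - t

    # --- costing ---------------------------------------------------------
    t = time.time()
    episodes_imp = impute_assessment_costs(episodes, config)
    model = fit_cost_model(episodes_imp, config, mff)
    costs = combine_costs(episodes_imp, model, mff, config)
    cells = incidence_table[["age", "gender"]].drop_duplicates()
    mean_costs = compute_mean_cost_table(costs, config, cells)
    logger.info("costing: fitted on %d episodes (%d patients), %d cells "
                "pooled", model.n_episodes, model.n_patients,
                int(mean_costs["pooled_flag"].sum()))
    timings["costing"] = time.time() - t

    # --- aggregation + Monte Carlo --------------------------------------
    t = time.time()
    estimates = aggregate_costs(incidence_table, mean_costs, population)
    mc, area_ci = monte_carlo_intervals(
        model, costs, incidence_table, population, mff, config, seed + 2)
    estimates = estimates.merge(area_ci[["area_id", "ci_low", "ci_high"]],
                                on="area_id")
    timings["estimate"] = time.time() - t

    # --- sensitivity -----------------------------------------------------
    t = time.time()
    centre_areas = [CENTRE_AREA_IDS[c] for c in ("A", "B", "C")]
    adjusted = {}
    for kind, factors in (
        ("suicide", suicide_adjustment_factors(suicide_asr, centre_areas)),
        ("rurality", rurality_adjustment_factors(rurality, config)),
    ):
        inc_adj = apply_adjustment(incidence_table, factors)
        est_adj = aggregate_costs(inc_adj, mean_costs, population)
        mc_adj, ci_adj = monte_carlo_intervals(
            model, costs, inc_adj, population, mff, config, seed + 2)
        est_adj = est_adj.merge(ci_adj[["area_id", "ci_low", "ci_high"]],
                                on="area_id")
        est_adj.insert(0, "mode", kind)
        adjusted[kind] = {
            "estimates": est_adj,
            "episodes_total": float(
                inc_adj["expected_presentations"].sum()),
            "total_cost": float(est_adj["total_cost"].sum()),
            "ci": (float(mc_adj.national_ci[0]),
                   float(mc_adj.national_ci[1])),
        }
    timings["sensitivity"] = time.time() - t

    deaths = synthetic_deaths_by_gender(suicide_asr, population,
                                        national_areas)
    ratios = per_suicide_ratios(
        totals["episodes_by_gender"],
        totals.get("patients_by_gender", {g: float("nan") for g in deaths}),
        deaths,
    )

    national_summary = {
        "episodes_total": totals["episodes_total"],
        "episodes_by_gender": totals["episodes_by_gender"],
        "patients_total": totals.get("patients_total"),
        "total_cost": float(estimates["total_cost"].sum()),
        "total_cost_ci": [mc.national_ci[0], mc.national_ci[1]],
        "total_cost_2017": inflate_to_year(
            float(estimates["total_cost"].sum()),
            config.inflation_factor_2017),
        "adjusted": {
            k: {kk: vv for kk, vv in v.items() if kk != "estimates"}
            for k, v in adjusted.items()
        },
    }

    tables = {
        "rates": rates,
        "incidence": incidence_table,
        "mean_costs": mean_costs,
        "ccg_estimates": estimates,
        "sensitivity_estimates": pd.concat(
            [adjusted["suicide"]["estimates"],
             adjusted["rurality"]["estimates"]], ignore_index=True),
        "per_suicide_ratios": ratios,
    }
    if synth_preset is not None:
        tables |= {"episodes": episodes, "population": population,
                   "mff": mff, "suicide_asr": suicide_asr,
                   "rurality": rurality}
    manifest = sio.write_outputs(tables, out, config, seed)
    model.to_json(out / "cost_model.json")
    manifest["inputs"] = input_digests
    manifest["timings"] = {k: round(v, 3) for k, v in timings.items()}
    manifest["package_version"] = __version__
    config.to_yaml(out / "config_resolved.yaml")

    return {
        "episodes": episodes,
        "population": population,
        "mff": mff,
        "suicide_asr": suicide_asr,
        "rurality": rurality,
        "rates": rates,
        "incidence": incidence_table,
        "totals": totals,
        "model": model,
        "mean_costs": mean_costs,
        "estimates": estimates,
        "mc": mc,
        "adjusted": adjusted,
        "ratios": ratios,
        "national_summary": national_summary,
        "manifest": manifest,
    }


def report(results: dict, config: PipelineConfig | None = None) -> str:
    """Human-readable markdown summary of a pipeline run."""
    config = config or PipelineConfig()
    s = results.get("national_summary", {})
    est = results.get("estimates")
    lines = ["# Self-harm hospital burden — run summary", ""]
    if est is None or not len(est):
        lines.append("No area estimates produced (zero areas).")
        return "\n".join(lines)

    eps = s["episodes_total"]
    by_g = s["episodes_by_gender"]
    shares = {g: round(100 * v / eps) if eps else 0 for g, v in by_g.items()}
    # largest-remainder style fix so printed shares sum to 100
    drift = 100 - sum(shares.values())
    if shares and drift:
        top = max(by_g, key=by_g.get)
        shares[top] += drift
    lines += [
        f"- Estimated presentations: {eps:,.0f} "
        + "(" + ", ".join(f"{shares[g]}% {g}" for g in sorted(shares)) + ")",
    ]
    if s.get("patients_total") is not None:
        lines.append(f"- Estimated patients: {s['patients_total']:,.0f}")
    lo, hi = s["total_cost_ci"]
    lines += [
        f"- Hospital costs: £{as_million(s['total_cost'])} million "
        f"(95% CI {as_million(lo)}−{as_million(hi)})",
        f"- In 2017 prices: £{as_million(s['total_cost_2017'])} million "
        f"(factor {config.inflation_factor_2017})",
    ]
    for kind, adj in s.get("adjusted", {}).items():
        alo, ahi = adj["ci"]
        lines.append(
            f"- {kind.capitalize()}-adjusted: "
            f"{adj['episodes_total']:,.0f} presentations, "
            f"£{as_million(adj['total_cost'])} million "
            f"(95% CI {as_million(alo)}−{as_million(ahi)})"
        )
    ratios = results.get("ratios")
    if ratios is not None and len(ratios):
        rt = ratios.set_index(["stratum", "measure"])["ratio"]
        if ("total", "episodes") in rt.index:
            lines.append(
                f"- Presentations per suicide: {rt[('total', 'episodes')]}"
                f" (patients per suicide: {rt[('total', 'patients')]})"
            )
    ranked = est.sort_values("presentations_per_1000")
    lines += [
        "",
        "Top area by presentations per 1,000: "
        f"{ranked.iloc[-1]['area_id']} "
        f"({ranked.iloc[-1]['presentations_per_1000']:.2f}); lowest: "
        f"{ranked.iloc[0]['area_id']} "
        f"({ranked.iloc[0]['presentations_per_1000']:.2f}).",
    ]
    return "\n".join(lines)
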