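"""Univariate sensitivity analyses: suicide-rate and rurality calibration.

Each analysis rescales the baseline incidence with one multiplicative
factor table (area suicide rate over the three-centre average, by gender;
or the rural-share interpolation to 31%/26% reductions), re-aggregates
costs with the unchanged mean-cost table, and re-runs the Monte-Carlo
interval. Writes sensitivity_estimates.csv.
"""

from pathlib import Path

import pandas as pd

from selfharm_burden import io as sio
from selfharm_burden.aggregate import (
    aggregate_costs,
    as_million,
    monte_carlo_intervals,
)
from selfharm_burden.config import PipelineConfig
from selfharm_burden.costing import (
    CENTRE_AREA_IDS,
    CostModel,
    combine_costs,
    impute_assessment_costs,
)
from selfharm_burden.sensitivity import (
    apply_adjustment,
    rurality_adjustment_factors,
    suicide_adjustment_factors,
)

IN = Path("results/analysis/inputs")
OUT = Path("results/analysis")
SEED = 2015


def main() -> None:
    cfg = PipelineConfig(mc_iterations=10_000)
    episodes, _ = sio.read_episode_table(IN / "episodes.csv")
    population = sio.read_population_table(IN / "population.csv")
    mff = sio.read_mff(IN / "mff.csv")
    incidence = pd.read_csv(OUT / "incidence.csv")
    mean_costs = pd.read_csv(OUT / "mean_costs.csv")
    model = CostModel.from_json(OUT / "cost_model.json")
    episodes = impute_assessment_costs(episodes, cfg)
    costs = combine_costs(episodes, model, mff, cfg)

    baseline_pres = incidence["expected_presentations"].sum()
    centre_areas = [CENTRE_AREA_IDS[c] for c in ("A", "B", "C")]
    frames = []
    for kind, factors in (
        ("suicide", suicide_adjustment_factors(
            sio.read_suicide_rates(IN / "suicide_asr.csv"), centre_areas)),
        ("rurality", rurality_adjustment_factors(
            sio.read_rurality(IN / "rurality.csv"), cfg)),
    ):
        adjusted = apply_adjustment(incidence, factors)
        est = aggregate_costs(adjusted, mean_costs, population)
        mc, ci = monte_carlo_intervals(
            model, costs, adjusted, population, mff, cfg, SEED)
        est = est.merge(ci[["area_id", "ci_low", "ci_high"]], on="area_id")
        est.insert(0, "mode", kind)
        frames.append(est)
        pres = adjusted["expected_presentations"].sum()
        lo, hi = mc.national_ci
        print(f"{kind}-adjusted: {pres:,.0f} presentations "
              f"({100 * pres / baseline_pres - 100:+.1f}% vs baseline), "
              f"£{as_million(est['total_cost'].sum())}M "
              f"(95% CI {as_million(lo)}−{as_million(hi)})")

    sio.write_outputs(
        {"sensitivity_estimates": pd.concat(frames, ignore_index=True)},
        OUT, cfg, SEED)


if __name__ == "__main__":
    main()
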