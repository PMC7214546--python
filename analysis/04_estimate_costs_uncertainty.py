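"""Combine incidence and mean costs into area totals with Monte-Carlo CIs.

Multiplies expected presentations by mean cost per cell for every area,
then propagates cost-model coefficient uncertainty (10,000 multivariate-
normal draws) into percentile intervals, and writes ccg_estimates.csv and
national_summary.json.
"""

import json
from pathlib import Path

import pandas as pd

from selfharm_burden import io as sio
from selfharm_burden.aggregate import (
    aggregate_costs,
    as_million,
    inflate_to_year,
    monte_carlo_intervals,
)
from selfharm_burden.config import PipelineConfig
from selfharm_burden.costing import (
    CostModel,
    combine_costs,
    impute_assessment_costs,
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
    estimates = aggregate_costs(incidence, mean_costs, population)
    mc, area_ci = monte_carlo_intervals(
        model, costs, incidence, population, mff, cfg, SEED)
    estimates = estimates.merge(area_ci[["area_id", "ci_low", "ci_high"]],
                                on="area_id")

    total = estimates["total_cost"].sum()
    summary = {
        "total_cost": total,
        "total_cost_ci": list(mc.national_ci),
        "total_cost_2017": inflate_to_year(total, cfg.inflation_factor_2017),
        "mc_iterations": mc.n_iter,
    }
    sio.write_outputs({"ccg_estimates": estimates}, OUT, cfg, SEED)
    (OUT / "national_summary.json").write_text(json.dumps(summary, indent=2))

    lo, hi = mc.national_ci
    print(f"national hospital cost: £{as_million(total)}M "
          f"(95% CI {as_million(lo)}−{as_million(hi)}) over "
          f"{len(estimates)} areas")
    print(f"in 2017 prices: £{as_million(summary['total_cost_2017'])}M")
    ranked = estimates.sort_values("cost_per_1000")
    print(f"cost per 1,000 population ranges "
          f"£{ranked['cost_per_1000'].iloc[0]:,.0f} "
          f"({ranked['area_id'].iloc[0]}) to "
          f"£{ranked['cost_per_1000'].iloc[-1]:,.0f} "
          f"({ranked['area_id'].iloc[-1]})")


if __name__ == "__main__":
    main()
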