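"""Fit the episode-cost model and build the mean-cost table.

Adds the psychosocial-assessment unit cost where the recorded cost
excludes it, fits the Gamma log-link GLM with patient-clustered standard
errors on the two cost-observed centres, transfers predictions to the
cost-missing centre with the price-index ratio, and writes
cost_model.json and mean_costs.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from selfharm_burden import io as sio
from selfharm_burden.config import PipelineConfig
from selfharm_burden.costing import (
    combine_costs,
    compute_mean_cost_table,
    fit_cost_model,
    impute_assessment_costs,
)

IN = Path("results/analysis/inputs")
OUT = Path("results/analysis")


def main() -> None:
    cfg = PipelineConfig()
    episodes, _ = sio.read_episode_table(IN / "episodes.csv")
    mff = sio.read_mff(IN / "mff.csv")

    episodes = impute_assessment_costs(episodes, cfg)
    model = fit_cost_model(episodes, cfg, mff)
    costs = combine_costs(episodes, model, mff, cfg)
    mean_costs = compute_mean_cost_table(costs, cfg)

    sio.write_outputs({"mean_costs": mean_costs}, OUT, cfg)
    model.to_json(OUT / "cost_model.json")

    se = pd.Series(np.sqrt(np.diag(model.vcov)), index=model.beta.index)
    print(f"fitted on {model.n_episodes} episodes from "
          f"{model.n_patients} patients; dispersion {model.dispersion:.3f}")
    for name in model.beta.index:
        print(f"  {name:>14}: {model.beta[name]: .4f} (se {se[name]:.4f})")
    print(f"mean observed cost £{costs.loc[costs.centre != 'C', 'final_cost'].mean():,.0f}; "
          f"mean predicted cost (centre C) "
          f"£{costs.loc[costs.centre == 'C', 'final_cost'].mean():,.0f}")
    print(f"{int(mean_costs['pooled_flag'].sum())} of {len(mean_costs)} "
          "age-gender cells pooled to a wider band")


if __name__ == "__main__":
    main()
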