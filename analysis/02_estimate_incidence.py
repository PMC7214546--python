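"""Estimate sentinel presentation rates and extrapolate to every area.

Reads the synthetic inputs from step 01, divides episode counts by the
catchment population per single year of age and gender, multiplies the
rates into each area's pyramid, and writes rates.csv and incidence.csv.
"""

from pathlib import Path

from selfharm_burden import io as sio
from selfharm_burden.config import PipelineConfig
from selfharm_burden.incidence import (
    CATCHMENT_AREA_ID,
    estimate_rates,
    extrapolate_incidence,
    national_totals,
)

IN = Path("results/analysis/inputs")
OUT = Path("results/analysis")


def main() -> None:
    cfg = PipelineConfig()
    episodes, _ = sio.read_episode_table(IN / "episodes.csv")
    population = sio.read_population_table(IN / "population.csv")

    catchment = population[population["area_id"] == CATCHMENT_AREA_ID]
    rates = estimate_rates(episodes, catchment, cfg.age_cap)
    areas = population[population["area_id"] != CATCHMENT_AREA_ID]
    incidence = extrapolate_incidence(rates, areas, cfg.age_cap)
    totals = national_totals(incidence, episodes)

    sio.write_outputs({"rates": rates, "incidence": incidence}, OUT, cfg)
    print(f"rate cells: {len(rates)} "
          f"(peak male rate at age "
          f"{rates[rates.gender == 'male'].nlargest(1, 'rate')['age'].iloc[0]})")
    print(f"national presentations: {totals['episodes_total']:,.0f} "
          f"({100 * totals['episodes_by_gender']['female'] / totals['episodes_total']:.0f}% female), "
          f"patients: {totals['patients_total']:,.0f}")


if __name__ == "__main__":
    main()
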