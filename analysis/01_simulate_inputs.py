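"""Generate the synthetic study inputs.

Draws one year of episode-level presentations for the three sentinel
centres (contrasting case-mix, Gamma costs with known log-linear
structure, patient-level repeat episodes) plus the synthetic geography
(population pyramids, price indices, suicide rates, rural fractions),
and writes the five input tables under results/analysis/inputs/.
"""

from pathlib import Path

import yaml

from selfharm_burden import io as sio
from selfharm_burden.synth import default_truth, generate_episodes, generate_geography

SEED = 2013
OUT = Path("results/analysis/inputs")


def main() -> None:
    truth = default_truth("faithful")
    episodes = generate_episodes(truth, SEED)
    population, mff, asr, rurality = generate_geography(truth, SEED + 1)
    sio.write_outputs(
        {"episodes": episodes, "population": population, "mff": mff,
         "suicide_asr": asr, "rurality": rurality},
        OUT, seed=SEED,
    )
    (OUT / "ground_truth.yaml").write_text(
        yaml.safe_dump(truth.to_dict(), sort_keys=False))

    n_rep = len(episodes) - episodes["patient_id"].nunique()
    print(f"episodes: {len(episodes)} across "
          f"{episodes['centre'].nunique()} centres "
          f"({n_rep} repeat episodes)")
    print(f"areas: {population['area_id'].nunique() - 1} + catchment; "
          f"catchment population "
          f"{population.loc[population.area_id == 'CATCHMENT', 'population'].sum():,.0f}")
    print(f"inputs written to {OUT}/")


if __name__ == "__main__":
    main()
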