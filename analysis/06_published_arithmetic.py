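"""Reporting arithmetic on the published 2013 national figures.

Recomputes, through the package's reporting operations, the
presentations-per-suicide and patients-per-suicide ratios from the
published national totals and registered suicide deaths, and the
2017-price uprating of the published national cost. Writes
published_arithmetic.csv.
"""

from pathlib import Path

from selfharm_burden import io as sio
from selfharm_burden.aggregate import as_million, inflate_to_year, per_suicide_ratios

OUT = Path("results/analysis")

EPISODES_2013 = 228_075.0
PATIENTS_2013 = 159_857.0
MALE_SHARE = 0.39
SUICIDES_2013 = {"male": 3688.0, "female": 1039.0}
COST_2013_MILLION = 128.6
INFLATION_2017 = 1.04062


def main() -> None:
    episodes = {"male": MALE_SHARE * EPISODES_2013,
                "female": (1 - MALE_SHARE) * EPISODES_2013}
    patients = {"male": MALE_SHARE * PATIENTS_2013,
                "female": (1 - MALE_SHARE) * PATIENTS_2013}
    ratios = per_suicide_ratios(episodes, patients, SUICIDES_2013)
    sio.write_outputs({"published_arithmetic": ratios}, OUT)

    table = ratios.set_index(["stratum", "measure"])["ratio"]
    print(f"presentations per suicide: {table[('total', 'episodes')]} "
          f"(male {table[('male', 'episodes')]}, "
          f"female {table[('female', 'episodes')]})")
    print(f"patients per suicide: {table[('total', 'patients')]} "
          f"(male {table[('male', 'patients')]}, "
          f"female {table[('female', 'patients')]})")
    inflated = as_million(inflate_to_year(COST_2013_MILLION * 1e6,
                                          INFLATION_2017))
    print(f"£{COST_2013_MILLION}M at 2013/14 prices = £{inflated}M "
          f"in 2017 prices (factor {INFLATION_2017})")


if __name__ == "__main__":
    main()
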