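"""Synthetic episode and geography generator with known ground truth.

The confidential sentinel data cannot be shared, so this module emulates
them: three hospital centres with contrasting case-mix (centre A assesses
73% and admits 78% of episodes, centre C only 50% and 37%, bracketing the
published range of sentinel-centre contrasts), Gamma-distributed episode costs whose
mean is log-linear in gender, age, assessment, admission and self-harm
method, log-normal patient-level random effects shared across a patient's
repeat episodes, and a small synthetic geography of commissioning areas
with population pyramids, price indices, suicide rates and rural
fractions.  Every downstream estimate can be checked against closed-form
expectations derived from the generating parameters (``truth_report``).

Centre roles: A and B are cost-observed; B's recorded costs exclude the
psychosocial assessment (the cost model targets the assessment-inclusive
cost, so B's assessed episodes draw a Gamma with mean exp(x·beta) − c,
making the post-imputation mean exactly exp(x·beta)); C carries covariates
but no costs.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from selfharm_burden.config import GENDERS, METHODS, PipelineConfig
from selfharm_burden.costing import CENTRE_AREA_IDS, COEF_NAMES, design_matrix

CATCHMENT_AREA_ID = "CATCHMENT"

#: age bands as (low, high inclusive, probability); modal male band 40-49,
#: modal female band 19-29, matching the published banded distributions
_MALE_BANDS = [(10, 18, 0.10), (19, 29, 0.24), (30, 39, 0.20),
               (40, 49, 0.30), (50, 59, 0.08), (60, 84, 0.08)]
_FEMALE_BANDS = [(10, 18, 0.17), (19, 29, 0.28), (30, 39, 0.19),
                 (40, 49, 0.19), (50, 59, 0.09), (60, 84, 0.08)]


@dataclass
class CentreSpec:
    """Case-mix and catchment parameters of one sentinel centre."""

    centre: str
    n_episodes: int
    catchment_pop: float
    female_prob: float
    method_probs: tuple[float, float, float]  # poisoning, injury, both
    admit_prob: float
    assess_prob: float
    cost_observed: bool
    assessment_cost_included: bool
    mff: float = 1.0
    asr_male: float = 15.0   # suicides per 100,000 person-years
    asr_female: float = 4.5
    rural_fraction: float = 0.10
    age_bands_male: list = field(default_factory=lambda: list(_MALE_BANDS))
    age_bands_female: list = field(default_factory=lambda: list(_FEMALE_BANDS))

    @property
    def area_id(self) -> str:
        return CENTRE_AREA_IDS[self.centre]


@dataclass
class GeographySpec:
    """Parameters of the synthetic set of commissioning areas."""

    n_areas: int = 12
    area_pop_range: tuple[float, float] = (150_000.0, 500_000.0)
    mff_range: tuple[float, float] = (0.95, 1.12)
    asr_male_mean: float = 15.0
    asr_female_mean: float = 4.5
    asr_rel_spread: float = 0.30  # half-width of the uniform rate multiplier
    max_rural_fraction: float = 0.80
    price_variation: bool = True  # False -> every MFF is exactly 1


@dataclass
class SyntheticGroundTruth:
    """Full generating model for episodes and geography."""

    centres: list[CentreSpec]
    #: log-scale cost coefficients (intercept, male, age/year, assessed,
    #: admitted, method contrasts vs poisoning)
    cost_beta: dict = field(default_factory=lambda: {
        "intercept": 6.109, "male": 0.10, "age": 0.008, "assessed": 0.35,
        "admitted": 0.90, "method_injury": -0.15, "method_both": 0.20,
    })
    gamma_shape: float = 2.0
    patient_effect_sd: float = 0.25
    repeat_prob: float = 0.12
    geography: GeographySpec = field(default_factory=GeographySpec)
    age_cap: int = 90
    assessment_unit_cost_child: float = 392.0
    assessment_unit_cost_adult: float = 228.0
    child_age_threshold: int = 18

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if not 0 <= self.repeat_prob <= 1:
            raise ValueError("repeat_prob must lie in [0, 1]")
        if self.patient_effect_sd < 0:
            raise ValueError("patient_effect_sd must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


def default_truth(preset: str = "faithful", **overrides) -> SyntheticGroundTruth:
    """Ground truth presets.

    ``faithful`` — three centres totalling 12,000 episodes over a two-
    million-person catchment (annual presentation rate ≈ 6 per 1,000,
    concentrated in ages 10–84) and 12 commissioning areas.
    ``tiny`` — 800 episodes, 6 areas, for smoke tests.
    """
    scale = {"faithful": 1.0, "tiny": 1 / 15}[preset]
    centres = [
        CentreSpec("A", round(3500 * scale), 600_000 * scale, 0.60,
                   (0.66, 0.27, 0.07), 0.78, 0.73, True, True,
                   mff=1.02, asr_male=12.0, asr_female=3.8,
                   rural_fraction=0.12),
        CentreSpec("B", round(3000 * scale), 520_000 * scale, 0.59,
                   (0.76, 0.19, 0.05), 0.55, 0.58, True, False,
                   mff=0.99, asr_male=15.0, asr_female=4.5,
                   rural_fraction=0.15),
        CentreSpec("C", round(5500 * scale), 900_000 * scale, 0.56,
                   (0.63, 0.30, 0.07), 0.37, 0.50, False, False,
                   mff=1.06, asr_male=18.0, asr_female=5.2,
                   rural_fraction=0.04),
    ]
    geography = GeographySpec(n_areas=12 if preset == "faithful" else 6)
    truth = SyntheticGroundTruth(centres=centres, geography=geography)
    return replace(truth, **overrides) if overrides else truth


def recovery_truth() -> SyntheticGroundTruth:
    """Exact-model benchmark world for coefficient recovery.

    Unlike the faithful case-mix preset, this world is designed so every
    cost coefficient is estimable with comparable precision from 5,000
    cost-observed episodes: balanced gender/service mixes and a roughly
    uniform method mix keep the worst-case asymptotic standard error near
    0.02 log-units, no patient effect and flat prices make the fitted
    mean model exactly the generating one.
    """
    centres = [
        CentreSpec("A", 2700, 600_000, 0.50, (0.34, 0.33, 0.33), 0.50,
                   0.50, True, True, mff=1.0),
        CentreSpec("B", 2300, 520_000, 0.50, (0.34, 0.33, 0.33), 0.50,
                   0.50, True, False, mff=1.0),
        CentreSpec("C", 500, 900_000, 0.50, (0.34, 0.33, 0.33), 0.50,
                   0.50, False, False, mff=1.0),
    ]
    return SyntheticGroundTruth(
        centres=centres,
        gamma_shape=3.0,
        patient_effect_sd=0.0,
        geography=GeographySpec(n_areas=6, price_variation=False),
    )


def _draw_band_ages(rng: np.random.Generator, bands: list, n: int) -> np.ndarray:
    """Ages drawn from a band mixture, uniform over integer years in band."""
    probs = np.array([w for _, _, w in bands], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(bands), size=n, p=probs)
    lows = np.array([lo for lo, _, _ in bands])[idx]
    highs = np.array([hi for _, hi, _ in bands])[idx]
    return lows + rng.integers(0, highs - lows + 1)


def _assign_patients(
    rng: np.random.Generator, n: int, repeat_prob: float, prefix: str
) -> np.ndarray:
    """Patient labels with repeats.

    The first episode opens a new patient; each later episode is a repeat
    with probability ``repeat_prob``, in which case it is attached to a
    uniformly chosen patient (so a patient's episode count is roughly
    geometric — a simple stand-in for real repetition dynamics).
    """
    if n == 0:
        return np.array([], dtype=object)
    is_new = np.ones(n, dtype=bool)
    if n > 1:
        is_new[1:] = rng.random(n - 1) >= repeat_prob
    patient_idx = np.cumsum(is_new) - 1
    n_new = patient_idx[-1] + 1
    repeats = ~is_new
    patient_idx[repeats] = rng.integers(0, n_new, size=int(repeats.sum()))
    return np.array([f"{prefix}p{i:05d}" for i in patient_idx], dtype=object)


def generate_episodes(
    truth: SyntheticGroundTruth, seed: int
) -> pd.DataFrame:
    """Draw one year of episode records from the generating model."""
    rng = np.random.default_rng(seed)
    frames = []
    for spec in truth.centres:
        n = spec.n_episodes
        if n == 0:
            continue
        gender = np.where(rng.random(n) < spec.female_prob, "female", "male")
        # patients are assigned within gender strata and keep one age, so
        # repeat episodes by one patient carry consistent demographics
        age = np.empty(n, dtype=int)
        patient_id = np.empty(n, dtype=object)
        for g, bands in (("female", spec.age_bands_female),
                         ("male", spec.age_bands_male)):
            sel = np.flatnonzero(gender == g)
            pid = _assign_patients(rng, len(sel), truth.repeat_prob,
                                   f"{spec.centre}_{g[0]}_")
            patient_id[sel] = pid
            uniq, inverse = np.unique(pid, return_inverse=True)
            patient_age = _draw_band_ages(rng, bands, len(uniq))
            age[sel] = patient_age[inverse]
        method = rng.choice(METHODS, size=n, p=np.array(spec.method_probs))
        admitted = rng.random(n) < spec.admit_prob
        assessed = rng.random(n) < spec.assess_prob
        df = pd.DataFrame({
            "episode_id": [f"{spec.centre}{i:06d}" for i in range(n)],
            "patient_id": patient_id,
            "centre": spec.centre,
            "age": age,
            "gender": gender,
            "method": method,
            "admitted": admitted,
            "assessed": assessed,
        })
        # log-normal multiplicative patient effect, shared within patient
        patients = df["patient_id"].unique()
        effects = pd.Series(
            np.exp(rng.normal(0.0, truth.patient_effect_sd, size=len(patients))),
            index=patients,
        )
        centre_mff = spec.mff if truth.geography.price_variation else 1.0
        beta_vec = np.array([truth.cost_beta[k] for k in COEF_NAMES])
        mu = (
            np.exp(design_matrix(df, age_cap=truth.age_cap).to_numpy()
                   @ beta_vec)
            * centre_mff
            * df["patient_id"].map(effects).to_numpy()
        )
        if spec.cost_observed:
            target_mu = mu.copy()
            if not spec.assessment_cost_included:
                unit = np.where(
                    df["age"] < truth.child_age_threshold,
                    truth.assessment_unit_cost_child,
                    truth.assessment_unit_cost_adult,
                )
                sub = df["assessed"].to_numpy() * unit
                # keep the partial mean positive even in extreme cells
                target_mu = np.maximum(mu - sub, 0.05 * mu)
            k = truth.gamma_shape
            df["observed_cost"] = rng.gamma(k, target_mu / k)
            df["assessment_cost_included"] = spec.assessment_cost_included
        else:
            df["observed_cost"] = np.nan
            df["assessment_cost_included"] = False
        frames.append(df)
    if not frames:
        warnings.warn("degenerate ground truth: zero episodes generated")
        return pd.DataFrame(columns=[
            "episode_id", "patient_id", "centre", "age", "gender", "method",
            "admitted", "assessed", "observed_cost",
            "assessment_cost_included",
        ])
    return pd.concat(frames, ignore_index=True)


def _pyramid_shape(age_cap: int) -> np.ndarray:
    """Relative population by single year of age (broadly England-like)."""
    ages = np.arange(age_cap + 1)
    w = np.ones(age_cap + 1)
    w[ages < 18] = 1.10
    w[(ages >= 18) & (ages < 30)] = 1.30
    w[(ages >= 30) & (ages < 45)] = 1.25
    w[(ages >= 45) & (ages < 60)] = 1.20
    w[(ages >= 60) & (ages < 75)] = 0.90
    w[ages >= 75] = 0.45
    return w / w.sum()


def _area_population(
    rng: np.random.Generator, area_id: str, total: float, age_cap: int,
    tilt: float = 0.0,
) -> pd.DataFrame:
    """One area's pyramid; ``tilt`` skews it young (<0) or old (>0)."""
    shape = _pyramid_shape(age_cap)
    ages = np.arange(age_cap + 1)
    shape = shape * np.exp(tilt * (ages - ages.mean()) / ages.mean())
    shape = shape / shape.sum()
    rows = []
    for gender, share in (("male", 0.49), ("female", 0.51)):
        pop = np.round(shape * total * share)
        rows.append(pd.DataFrame({
            "area_id": area_id, "age": ages, "gender": gender,
            "population": pop,
        }))
    return pd.concat(rows, ignore_index=True)


def generate_geography(
    truth: SyntheticGroundTruth, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Population, MFF, suicide-rate and rurality tables.

    Emits the three centre areas, a designated catchment area that is the
    exact sum of the centre populations, and ``n_areas`` synthetic
    commissioning areas with varying size, age tilt, price index, suicide
    rates and rural fraction.
    """
    rng = np.random.default_rng(seed)
    geo = truth.geography
    pop_frames, mff_rows, asr_rows, rural_rows = [], [], [], []

    for spec in truth.centres:
        pop_frames.append(_area_population(
            rng, spec.area_id, spec.catchment_pop, truth.age_cap))
        mff_rows.append({"area_id": spec.area_id,
                         "mff": spec.mff if geo.price_variation else 1.0})
        asr_rows += [
            {"area_id": spec.area_id, "gender": "male", "asr": spec.asr_male},
            {"area_id": spec.area_id, "gender": "female",
             "asr": spec.asr_female},
        ]
        rural_rows.append({"area_id": spec.area_id,
                           "rural_fraction": spec.rural_fraction})

    catchment = (
        pd.concat(pop_frames)
        .groupby(["age", "gender"], as_index=False)["population"].sum()
    )
    catchment.insert(0, "area_id", CATCHMENT_AREA_ID)
    pop_frames.append(catchment)

    lo, hi = geo.area_pop_range
    for i in range(geo.n_areas):
        area = f"ccg_{i + 1:02d}"
        total = rng.uniform(lo, hi)
        tilt = rng.uniform(-0.35, 0.35)
        pop_frames.append(_area_population(rng, area, total, truth.age_cap,
                                           tilt))
        mff_rows.append({
            "area_id": area,
            "mff": float(rng.uniform(*geo.mff_range))
            if geo.price_variation else 1.0,
        })
        mult = rng.uniform(1 - geo.asr_rel_spread, 1 + geo.asr_rel_spread)
        asr_rows += [
            {"area_id": area, "gender": "male",
             "asr": geo.asr_male_mean * mult},
            {"area_id": area, "gender": "female",
             "asr": geo.asr_female_mean
             * rng.uniform(1 - geo.asr_rel_spread, 1 + geo.asr_rel_spread)},
        ]
        rural_rows.append({
            "area_id": area,
            "rural_fraction": float(
                rng.uniform(0.0, geo.max_rural_fraction)),
        })

    population = pd.concat(pop_frames, ignore_index=True)
    return (population, pd.DataFrame(mff_rows), pd.DataFrame(asr_rows),
            pd.DataFrame(rural_rows))


def _cell_probabilities(spec: CentreSpec, age_cap: int) -> pd.DataFrame:
    """P(age, gender) of an episode at one centre, in closed form."""
    rows = []
    for gender, bands, p_g in (
        ("male", spec.age_bands_male, 1 - spec.female_prob),
        ("female", spec.age_bands_female, spec.female_prob),
    ):
        total_w = sum(w for _, _, w in bands)
        for lo, hi, w in bands:
            width = hi - lo + 1
            for a in range(lo, min(hi, age_cap) + 1):
                rows.append({"age": a, "gender": gender,
                             "p": p_g * (w / total_w) / width})
    return (pd.DataFrame(rows)
            .groupby(["age", "gender"], as_index=False)["p"].sum())


def _pattern_factor(spec: CentreSpec, beta: dict) -> float:
    """E[exp(service/method part of x·beta)] by enumerating the 12 patterns."""
    total = 0.0
    method_beta = {"poisoning": 0.0, "injury": beta["method_injury"],
                   "both": beta["method_both"]}
    for m, pm in zip(METHODS, spec.method_probs):
        for adm, p_adm in ((1, spec.admit_prob), (0, 1 - spec.admit_prob)):
            for ass, p_ass in ((1, spec.assess_prob), (0, 1 - spec.assess_prob)):
                total += (pm * p_adm * p_ass
                          * np.exp(method_beta[m] + adm * beta["admitted"]
                                   + ass * beta["assessed"]))
    return total


def true_rate_table(
    truth: SyntheticGroundTruth, population: pd.DataFrame
) -> pd.DataFrame:
    """Generative presentation rate per person-year by (age, gender)."""
    expected = []
    for spec in truth.centres:
        p = _cell_probabilities(spec, truth.age_cap)
        p["expected"] = p["p"] * spec.n_episodes
        expected.append(p[["age", "gender", "expected"]])
    counts = (pd.concat(expected)
              .groupby(["age", "gender"], as_index=False)["expected"].sum())
    catch = population[population["area_id"] == CATCHMENT_AREA_ID]
    out = catch.merge(counts, on=["age", "gender"], how="left").fillna(
        {"expected": 0.0})
    out["rate"] = np.where(out["population"] > 0,
                           out["expected"] / out["population"], 0.0)
    return out[["age", "gender", "rate"]]


def true_mean_cost_table(truth: SyntheticGroundTruth) -> pd.DataFrame:
    """Generative E[cost | age, gender] marginal over centre and pattern."""
    beta = truth.cost_beta
    pe = np.exp(truth.patient_effect_sd ** 2 / 2)
    parts = []
    for spec in truth.centres:
        p = _cell_probabilities(spec, truth.age_cap)
        base = np.exp(beta["intercept"]
                      + beta["male"] * (p["gender"] == "male")
                      + beta["age"] * p["age"])
        w = p["p"] * spec.n_episodes
        centre_mff = spec.mff if truth.geography.price_variation else 1.0
        cost = base * _pattern_factor(spec, beta) * centre_mff * pe
        parts.append(pd.DataFrame({
            "age": p["age"], "gender": p["gender"],
            "w": w, "wc": w * cost,
        }))
    agg = (pd.concat(parts)
           .groupby(["age", "gender"], as_index=False)[["w", "wc"]].sum())
    agg["mean_cost"] = agg["wc"] / agg["w"]
    return agg[["age", "gender", "mean_cost"]]


def truth_report(
    truth: SyntheticGroundTruth, population: pd.DataFrame
) -> pd.DataFrame:
    """Closed-form expected presentations and costs per area (no sampling)."""
    rates = true_rate_table(truth, population)
    costs = true_mean_cost_table(truth)
    cells = population.merge(rates, on=["age", "gender"], how="left").fillna(
        {"rate": 0.0})
    cells = cells.merge(costs, on=["age", "gender"], how="left").fillna(
        {"mean_cost": 0.0})
    cells["expected_presentations"] = cells["rate"] * cells["population"]
    cells["expected_cost"] = (cells["expected_presentations"]
                              * cells["mean_cost"])
    out = (cells.groupby("area_id", as_index=False)
           [["expected_presentations", "expected_cost"]].sum())
    return out.sort_values("area_id").reset_index(drop=True)
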