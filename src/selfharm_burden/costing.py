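"""Episode-cost modelling.

Costs are observed at two centres only.  After adding the unit cost of a
psychosocial assessment to episodes whose recorded cost excludes it, a
generalised linear model with Gamma distribution and log link is fitted to
the cost-observed episodes, with one-way cluster-robust (patient) standard
errors to respect repeat episodes by the same individual.  The fitted
coefficients are transferred to the cost-missing centre, rescaled by the
ratio of Market Forces Factor price indices, and all episode costs are
finally summarised as mean cost per single year of age and gender, pooling
sparse cells into their 10-year band.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from selfharm_burden.config import (
    COST_MISSING_CENTRE,
    COST_OBSERVED_CENTRES,
    GENDERS,
    PipelineConfig,
)

logger = logging.getLogger(__name__)

#: area_id of each centre's own commissioning area in geography tables
CENTRE_AREA_IDS = {"A": "centre_A", "B": "centre_B", "C": "centre_C"}

#: coefficient order of the continuous-age design
COEF_NAMES = [
    "intercept",
    "male",
    "age",
    "assessed",
    "admitted",
    "method_injury",
    "method_both",
]


class FitError(RuntimeError):
    """Cost-model estimation failed (singular design or non-convergence)."""


def design_matrix(
    episodes: pd.DataFrame,
    age_as_bands: bool = False,
    age_cap: int = 90,
) -> pd.DataFrame:
    """Model matrix for the cost regression.

    Age enters per-year (continuous) by default, clamped at ``age_cap``;
    with ``age_as_bands`` it enters as 10-year band indicators against the
    youngest observed band.  Method contrasts are against self-poisoning,
    the modal class.
    """
    age = episodes["age"].clip(upper=age_cap)
    X = pd.DataFrame(index=episodes.index)
    X["intercept"] = 1.0
    X["male"] = (episodes["gender"] == "male").astype(float)
    if age_as_bands:
        band = (age // 10) * 10
        ref = int(band.min())
        for b in sorted(band.unique()):
            if b == ref:
                continue
            X[f"age_band_{int(b)}"] = (band == b).astype(float)
    else:
        X["age"] = age.astype(float)
    X["assessed"] = episodes["assessed"].astype(float)
    X["admitted"] = episodes["admitted"].astype(float)
    X["method_injury"] = (episodes["method"] == "injury").astype(float)
    X["method_both"] = (episodes["method"] == "both").astype(float)
    return X


@dataclass
class CostModel:
    """Fitted Gamma log-link cost model with cluster-robust covariance."""

    beta: pd.Series
    vcov: pd.DataFrame
    dispersion: float
    fit_mff: float
    n_episodes: int
    n_patients: int
    age_as_bands: bool = False
    age_cap: int = 90
    n_excluded_nonpositive: int = 0
    converged: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.beta.index) != list(self.vcov.index) or list(
            self.beta.index
        ) != list(self.vcov.columns):
            raise ValueError("beta and vcov dimensions disagree")
        V = self.vcov.to_numpy()
        if not np.allclose(V, V.T, atol=1e-8):
            raise ValueError("vcov is not symmetric")

    def linear_predictor(self, episodes: pd.DataFrame) -> np.ndarray:
        X = design_matrix(episodes, self.age_as_bands, self.age_cap)
        X = X.reindex(columns=self.beta.index, fill_value=0.0)
        return X.to_numpy() @ self.beta.to_numpy()

    def predict_mean(self, episodes: pd.DataFrame) -> np.ndarray:
        """Expected cost exp(x·beta), at the fitting centres' price level."""
        return np.exp(self.linear_predictor(episodes))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coef_names": list(self.beta.index),
            "beta": self.beta.to_numpy().tolist(),
            "vcov": self.vcov.to_numpy().tolist(),
            "dispersion": self.dispersion,
            "fit_mff": self.fit_mff,
            "n_episodes": self.n_episodes,
            "n_patients": self.n_patients,
            "age_as_bands": self.age_as_bands,
            "age_cap": self.age_cap,
            "n_excluded_nonpositive": self.n_excluded_nonpositive,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CostModel":
        d = json.loads(Path(path).read_text())
        names = d["coef_names"]
        return cls(
            beta=pd.Series(d["beta"], index=names),
            vcov=pd.DataFrame(d["vcov"], index=names, columns=names),
            dispersion=d["dispersion"],
            fit_mff=d["fit_mff"],
            n_episodes=d["n_episodes"],
            n_patients=d["n_patients"],
            age_as_bands=d["age_as_bands"],
            age_cap=d["age_cap"],
            n_excluded_nonpositive=d["n_excluded_nonpositive"],
        )


def impute_assessment_costs(
    episodes: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Add the psychosocial-assessment unit cost where it is not included.

    Applies only to assessed episodes whose recorded cost excludes the
    assessment; the inclusion flag is flipped afterwards, making the
    operation idempotent.
    """
    out = episodes.copy()
    target = (
        out["assessed"]
        & ~out["assessment_cost_included"]
        & out["observed_cost"].notna()
    )
    child = out["age"] < config.child_age_threshold
    out.loc[target & child, "observed_cost"] += config.assessment_unit_cost_child
    out.loc[target & ~child, "observed_cost"] += config.assessment_unit_cost_adult
    out.loc[target, "assessment_cost_included"] = True
    return out


def _fit_mff_for_centres(
    episodes: pd.DataFrame, mff: pd.DataFrame | None
) -> float:
    """Episode-weighted mean price index of the fitting centres."""
    if mff is None:
        return 1.0
    lookup = mff.set_index("area_id")["mff"]
    values = episodes["centre"].map(
        lambda c: lookup.get(CENTRE_AREA_IDS.get(c, c), np.nan)
    )
    if values.isna().any():
        raise KeyError("MFF missing for one of the fitting centres")
    return float(values.mean())


def fit_cost_model(
    episodes: pd.DataFrame,
    config: PipelineConfig | None = None,
    mff: pd.DataFrame | None = None,
) -> CostModel:
    """Fit the Gamma log-link GLM on the cost-observed centres.

    Standard errors use the one-way cluster-robust sandwich over patients.
    Episodes with non-positive cost are excluded from fitting (the Gamma
    support is positive) with a logged count.
    """
    config = config or PipelineConfig()
    df = episodes[episodes["centre"].isin(COST_OBSERVED_CENTRES)].copy()
    if df.empty:
        raise FitError("no cost-observed episodes to fit on")
    nonpos = ~(df["observed_cost"] > 0)
    n_excluded = int(nonpos.sum())
    if n_excluded:
        logger.warning("excluding %d non-positive costs from fitting",
                       n_excluded)
    df = df[~nonpos]
    if df["patient_id"].nunique() < 2:
        raise FitError("need at least 2 patients to fit the cost model")

    X = design_matrix(df, config.age_as_bands, config.age_cap)
    Xv = X.to_numpy()
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        varless = [c for c in X.columns if c != "intercept"
                   and X[c].nunique() == 1]
        raise FitError(
            f"singular design (rank {rank} < {Xv.shape[1]}); "
            f"constant columns: {varless or 'collinear combination'}"
        )

    y = df["observed_cost"].to_numpy()
    groups = pd.factorize(df["patient_id"])[0]
    model = sm.GLM(y, Xv, family=sm.families.Gamma(sm.families.links.Log()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels domain warnings
        res = model.fit(
            cov_type="cluster",
            cov_kwds={"groups": groups},
            maxiter=200,
            tol=1e-10,
        )
    if not res.converged:
        raise FitError(
            f"IRLS did not converge in {res.fit_history['iteration']} "
            f"iterations; deviance trace {res.fit_history['deviance'][-5:]}"
        )
    names = list(X.columns)
    beta = pd.Series(res.params, index=names)
    vcov = pd.DataFrame(res.cov_params(), index=names, columns=names)
    # symmetrise against floating-point asymmetry from the sandwich product
    vcov = (vcov + vcov.T) / 2
    dispersion = float(res.pearson_chi2 / res.df_resid)
    return CostModel(
        beta=beta,
        vcov=vcov,
        dispersion=dispersion,
        fit_mff=_fit_mff_for_centres(df, mff),
        n_episodes=int(len(df)),
        n_patients=int(df["patient_id"].nunique()),
        age_as_bands=config.age_as_bands,
        age_cap=config.age_cap,
        n_excluded_nonpositive=n_excluded,
    )


def predict_missing_centre_costs(
    model: CostModel,
    episodes: pd.DataFrame,
    mff: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Transfer the fitted model to episodes without observed costs.

    predicted_cost = exp(x·beta) × mff_target / mff_fit — predictions are
    rescaled from the fitting centres' price level to the target area's.
    Ages beyond the model's cap are clamped with a warning.
    """
    config = config or PipelineConfig()
    out = episodes.copy()
    n_clamped = int((out["age"] > model.age_cap).sum())
    if n_clamped:
        warnings.warn(
            f"{n_clamped} episode(s) older than the age cap "
            f"{model.age_cap}; clamped for prediction"
        )
    mu = np.exp(model.linear_predictor(out))
    if mff is not None:
        lookup = mff.set_index("area_id")["mff"]
        target = out["centre"].map(
            lambda c: lookup.get(CENTRE_AREA_IDS.get(c, c), np.nan)
        )
        if target.isna().any():
            raise KeyError("MFF missing for a prediction target centre")
        mu = mu * target.to_numpy() / model.fit_mff
    out["predicted_cost"] = mu
    return out


def combine_costs(
    episodes: pd.DataFrame,
    model: CostModel | None = None,
    mff: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Attach one ``final_cost`` per episode.

    Default: observed (post-imputation) cost for the cost-observed
    centres, model prediction for the cost-missing centre.  With
    ``config.predict_all_centres`` the model prediction is used for every
    episode.
    """
    config = config or PipelineConfig()
    out = episodes.copy()
    need_prediction = (
        pd.Series(True, index=out.index)
        if config.predict_all_centres
        else out["centre"].eq(COST_MISSING_CENTRE)
    )
    if need_prediction.any():
        if model is None:
            raise ValueError("a fitted CostModel is required for prediction")
        pred = predict_missing_centre_costs(
            model, out.loc[need_prediction], mff, config
        )["predicted_cost"]
        out.loc[need_prediction, "final_cost"] = pred
    out.loc[~need_prediction, "final_cost"] = out.loc[
        ~need_prediction, "observed_cost"
    ]
    return out


def pooling_assignments(
    costs: pd.DataFrame,
    config: PipelineConfig,
    cells: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map every (age, gender) cell to the episode group it averages over.

    Cells with at least ``cost_cell_min_n`` contributing episodes use their
    own episodes; sparser cells fall back to their 10-year age band, then
    to the gender-wide pool.  Returns

    ``cell_groups``   one row per requested cell with columns
                      [age, gender, level, group_age, n, pooled_flag]
                      where level is "cell" / "band" / "gender";
    ``episode_keys``  per input episode its capped age, band and gender.
    """
    ep = costs.copy()
    ep["age_c"] = ep["age"].clip(upper=config.age_cap).astype(int)
    ep["band"] = (ep["age_c"] // 10) * 10
    counts = ep.groupby(["age_c", "gender"]).size()
    band_counts = ep.groupby(["band", "gender"]).size()
    gender_counts = ep.groupby("gender").size()

    if cells is None:
        cells = (
            ep[["age_c", "gender"]]
            .drop_duplicates()
            .rename(columns={"age_c": "age"})
        )
    rows = []
    for age, gender in cells[["age", "gender"]].itertuples(index=False):
        age_c = min(int(age), config.age_cap)
        band = (age_c // 10) * 10
        n = int(counts.get((age_c, gender), 0))
        if n >= config.cost_cell_min_n:
            level, group_age = "cell", age_c
        elif int(band_counts.get((band, gender), 0)) > 0:
            level, group_age = "band", band
        elif int(gender_counts.get(gender, 0)) > 0:
            level, group_age = "gender", -1
        else:
            raise ValueError(
                f"no cost data at all for gender {gender!r}: cannot pool"
            )
        rows.append({
            "age": int(age), "gender": gender, "level": level,
            "group_age": group_age, "n": n,
            "pooled_flag": level != "cell",
        })
    cell_groups = pd.DataFrame(rows)
    episode_keys = ep[["age_c", "band", "gender"]]
    return cell_groups, episode_keys


def compute_mean_cost_table(
    costs: pd.DataFrame,
    config: PipelineConfig | None = None,
    cells: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean cost per presentation by single year of age and gender.

    ``costs`` must carry one cost per episode in ``final_cost``.  If
    ``cells`` is given (columns age, gender), a mean is produced for every
    requested cell, pooling as needed; otherwise for every populated cell.
    """
    config = config or PipelineConfig()
    if "final_cost" not in costs.columns:
        raise ValueError("costs frame must carry a final_cost column")
    if costs["final_cost"].isna().any():
        raise ValueError("every episode must carry exactly one cost")
    cell_groups, keys = pooling_assignments(costs, config, cells)
    y = costs["final_cost"].to_numpy()

    cell_mean = (
        pd.Series(y, index=pd.MultiIndex.from_frame(keys[["age_c", "gender"]]))
        .groupby(level=[0, 1]).mean()
    )
    band_mean = (
        pd.Series(y, index=pd.MultiIndex.from_frame(keys[["band", "gender"]]))
        .groupby(level=[0, 1]).mean()
    )
    gender_mean = (
        pd.Series(y, index=keys["gender"]).groupby(level=0).mean()
    )

    def lookup(row: pd.Series) -> float:
        if row["level"] == "cell":
            return float(cell_mean[(row["group_age"], row["gender"])])
        if row["level"] == "band":
            return float(band_mean[(row["group_age"], row["gender"])])
        return float(gender_mean[row["gender"]])

    out = cell_groups.copy()
    out["mean_cost"] = out.apply(lookup, axis=1)
    return out[["age", "gender", "mean_cost", "n", "pooled_flag"]]
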