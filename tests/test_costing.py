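"""Cost imputation, Gamma GLM fitting, transfer and the mean-cost table."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from selfharm_burden.config import PipelineConfig
from selfharm_burden.costing import (
    COEF_NAMES,
    CostModel,
    FitError,
    combine_costs,
    compute_mean_cost_table,
    design_matrix,
    fit_cost_model,
    impute_assessment_costs,
    predict_missing_centre_costs,
)
from selfharm_burden.synth import default_truth, generate_episodes


def _episode(age, assessed, cost, included, centre="B", **kw):
    base = {
        "episode_id": "e0", "patient_id": "p0", "centre": centre,
        "age": age, "gender": "female", "method": "poisoning",
        "admitted": False, "assessed": assessed, "observed_cost": cost,
        "assessment_cost_included": included,
    }
    base.update(kw)
    return base


@pytest.mark.parametrize("age,assessed,included,expected", [
    (16, True, False, 892.0),   # child rate 392 added
    (30, True, False, 728.0),   # adult rate 228 added
    (30, False, False, 500.0),  # not assessed: unchanged
    (30, True, True, 500.0),    # already included: unchanged
])
def test_assessment_cost_imputation(age, assessed, included, expected):
    df = pd.DataFrame([_episode(age, assessed, 500.0, included)])
    out = impute_assessment_costs(df, PipelineConfig())
    assert out["observed_cost"].iloc[0] == expected


def test_imputation_idempotent():
    df = pd.DataFrame([_episode(30, True, 500.0, False)])
    cfg = PipelineConfig()
    once = impute_assessment_costs(df, cfg)
    twice = impute_assessment_costs(once, cfg)
    pd.testing.assert_frame_equal(once, twice)
    assert once["assessment_cost_included"].all()


def test_intercept_only_fit_recovers_sample_mean(tiny_world, config):
    """The Gamma log-link score equation forces the intercept-only fitted
    mean to equal the arithmetic sample mean."""
    import statsmodels.api as sm

    ep = impute_assessment_costs(tiny_world["episodes"], config)
    obs = ep[ep["centre"].isin(["A", "B"])]
    res = sm.GLM(
        obs["observed_cost"].to_numpy(),
        np.ones((len(obs), 1)),
        family=sm.families.Gamma(sm.families.links.Log()),
    ).fit(tol=1e-12)
    assert np.exp(res.params[0]) == pytest.approx(
        obs["observed_cost"].mean(), rel=1e-8)


def test_score_equation_vanishes_at_fit(fitted_model):
    """At beta-hat the Gamma log-link quasi-score sums to ~zero."""
    episodes, model = fitted_model
    obs = episodes[episodes["centre"].isin(["A", "B"])]
    X = design_matrix(obs, model.age_as_bands, model.age_cap).to_numpy()
    y = obs["observed_cost"].to_numpy()
    mu = np.exp(X @ model.beta.to_numpy())
    score = X.T @ ((y - mu) / mu)
    assert np.abs(score).max() < 1e-6 * len(obs)


def test_cost_scale_equivariance(tiny_world, config):
    """Multiplying all costs by c shifts only the intercept (by log c)."""
    ep = impute_assessment_costs(tiny_world["episodes"], config)
    m1 = fit_cost_model(ep, config)
    scaled = ep.copy()
    scaled["observed_cost"] *= 3.0
    m2 = fit_cost_model(scaled, config)
    assert m2.beta["intercept"] - m1.beta["intercept"] == pytest.approx(
        np.log(3.0), abs=1e-6)
    others = [c for c in COEF_NAMES if c != "intercept"]
    np.testing.assert_allclose(m2.beta[others], m1.beta[others], atol=1e-6)


def test_clustered_se_exceeds_naive_under_correlation():
    """With a positive within-patient effect, patient-clustered standard
    errors for the intercept are at least the naive model-based ones."""
    wins = 0
    for seed in range(20):
        truth = default_truth("faithful", patient_effect_sd=0.6,
                              repeat_prob=0.35)
        truth.geography.price_variation = False
        ep = generate_episodes(truth, seed=1000 + seed)
        cfg = PipelineConfig()
        ep = impute_assessment_costs(ep, cfg)
        model = fit_cost_model(ep, cfg)

        import statsmodels.api as sm
        obs = ep[ep["centre"].isin(["A", "B"])]
        X = design_matrix(obs).to_numpy()
        naive = sm.GLM(
            obs["observed_cost"].to_numpy(), X,
            family=sm.families.Gamma(sm.families.links.Log()),
        ).fit()
        se_cluster = np.sqrt(model.vcov.iloc[0, 0])
        se_naive = naive.bse[0]
        wins += se_cluster >= se_naive
    assert wins >= 18  # allow sampling slack in at most 2 of 20 worlds


def test_singular_design_raises_naming_column(tiny_world, config):
    ep = tiny_world["episodes"].copy()
    ep["method"] = "poisoning"  # method contrasts become constant zero
    ep = impute_assessment_costs(ep, config)
    with pytest.raises(FitError, match="method"):
        fit_cost_model(ep, config)


def test_too_few_patients_raises(config):
    df = pd.DataFrame([_episode(30, False, 500.0, True, centre="A")])
    with pytest.raises(FitError, match="patients"):
        fit_cost_model(df, config)


def test_prediction_neutral_and_linear_in_mff(fitted_model, tiny_world):
    episodes, model = fitted_model
    target = episodes[episodes["centre"] == "C"].head(50)
    neutral_mff = pd.DataFrame({
        "area_id": ["centre_A", "centre_B", "centre_C"],
        "mff": [model.fit_mff] * 3,
    })
    neutral = predict_missing_centre_costs(model, target, neutral_mff)
    bare = np.exp(model.linear_predictor(target))
    np.testing.assert_allclose(neutral["predicted_cost"], bare, rtol=1e-12)

    doubled_mff = neutral_mff.assign(mff=neutral_mff["mff"] * 2)
    doubled = predict_missing_centre_costs(model, target, doubled_mff)
    np.testing.assert_allclose(doubled["predicted_cost"],
                               neutral["predicted_cost"] * 2, rtol=1e-12)
    assert (doubled["predicted_cost"] > 0).all()


def test_age_beyond_cap_clamped_with_warning(fitted_model):
    episodes, model = fitted_model
    target = episodes[episodes["centre"] == "C"].head(2).copy()
    target["age"] = [95, 40]
    with pytest.warns(UserWarning, match="age cap"):
        out = predict_missing_centre_costs(model, target)
    capped = target.copy()
    capped["age"] = [model.age_cap, 40]
    np.testing.assert_allclose(out["predicted_cost"],
                               np.exp(model.linear_predictor(capped)))


def test_transfer_prediction_close_to_generative_mean():
    """Predicted costs for the cost-missing centre average within 5% of
    the generating expectation when the model is exact."""
    truth = default_truth("faithful", patient_effect_sd=0.0)
    truth.geography.price_variation = False
    ep = generate_episodes(truth, seed=31)
    cfg = PipelineConfig()
    ep = impute_assessment_costs(ep, cfg)
    model = fit_cost_model(ep, cfg)
    target = ep[ep["centre"] == "C"]
    pred = predict_missing_centre_costs(model, target)["predicted_cost"]
    beta = np.array([truth.cost_beta[k] for k in COEF_NAMES])
    true_mean = np.exp(design_matrix(target).to_numpy() @ beta)
    assert pred.mean() == pytest.approx(true_mean.mean(), rel=0.05)


def test_mean_cost_constant_data():
    df = pd.DataFrame([
        _episode(a, False, 100.0, True, centre="A",
                 episode_id=f"e{a}", patient_id=f"p{a}")
        for a in (20, 21, 22, 23, 24, 30)
    ])
    df["final_cost"] = 250.0
    table = compute_mean_cost_table(df, PipelineConfig(cost_cell_min_n=1))
    assert (table["mean_cost"] == 250.0).all()


def test_mean_cost_weighted_identity(tiny_world, fitted_model, config):
    """Sum of cell mean x n equals total cost when nothing is pooled."""
    episodes, model = fitted_model
    costs = combine_costs(episodes, model, tiny_world["mff"], config)
    cfg1 = config.model_copy(update={"cost_cell_min_n": 1})
    table = compute_mean_cost_table(costs, cfg1)
    assert not table["pooled_flag"].any()
    assert (table["mean_cost"] * table["n"]).sum() == pytest.approx(
        costs["final_cost"].sum(), rel=1e-9)


def test_sparse_cell_pooled_to_band_mean():
    """A 2-episode cell with min_n = 5 takes its 10-year band mean."""
    rows = []
    for i, (age, cost) in enumerate([
        (42, 100.0), (42, 200.0),                          # sparse cell
        (45, 300.0), (45, 500.0), (45, 400.0), (45, 350.0), (45, 450.0),
        (47, 600.0), (47, 800.0), (47, 700.0),
    ]):
        rows.append(_episode(age, False, cost, True, centre="A",
                             episode_id=f"e{i}", patient_id=f"p{i}"))
    df = pd.DataFrame(rows)
    df["final_cost"] = df["observed_cost"]
    table = compute_mean_cost_table(df, PipelineConfig(cost_cell_min_n=5))
    cell = table[(table["age"] == 42)]
    band_mean = df["final_cost"].mean()  # all ten lie in band 40-49
    assert cell["pooled_flag"].iloc[0]
    assert cell["mean_cost"].iloc[0] == pytest.approx(band_mean)
    full = table[(table["age"] == 45)]
    assert not full["pooled_flag"].iloc[0]
    assert full["mean_cost"].iloc[0] == pytest.approx(400.0)


def test_empty_band_falls_back_to_gender_mean():
    rows = [
        _episode(20, False, 100.0, True, centre="A", episode_id=f"e{i}",
                 patient_id=f"p{i}")
        for i in range(6)
    ]
    df = pd.DataFrame(rows)
    df["final_cost"] = [90, 100, 110, 100, 95, 105]
    cells = pd.DataFrame({"age": [70], "gender": ["female"]})
    table = compute_mean_cost_table(df, PipelineConfig(), cells=cells)
    assert table["pooled_flag"].iloc[0]
    assert table["mean_cost"].iloc[0] == pytest.approx(100.0)


def test_model_json_round_trip(fitted_model, tmp_path):
    _, model = fitted_model
    path = tmp_path / "cost_model.json"
    model.to_json(path)
    back = CostModel.from_json(path)
    pd.testing.assert_series_equal(back.beta, model.beta)
    pd.testing.assert_frame_equal(back.vcov, model.vcov)
    assert back.fit_mff == model.fit_mff


def test_wald_interval_coverage_of_true_coefficients():
    """Cluster-robust 95% Wald intervals cover the generating coefficients
    at close to nominal rate over repeated exact-model worlds."""
    truth = default_truth("tiny", patient_effect_sd=0.0)
    truth.geography.price_variation = False
    beta_true = np.array([truth.cost_beta[k] for k in COEF_NAMES])
    cfg = PipelineConfig()
    covered = total = 0
    for seed in range(500):
        ep = generate_episodes(truth, seed=20_000 + seed)
        ep = impute_assessment_costs(ep, cfg)
        model = fit_cost_model(ep, cfg)
        se = np.sqrt(np.diag(model.vcov.to_numpy()))
        inside = np.abs(model.beta.to_numpy() - beta_true) <= 1.96 * se
        covered += inside.sum()
        total += len(inside)
    assert 0.93 <= covered / total <= 0.97
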