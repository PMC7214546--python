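"""Cost aggregation, Monte-Carlo intervals and reporting arithmetic."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from selfharm_burden.aggregate import (
    aggregate_costs,
    as_million,
    inflate_to_year,
    monte_carlo_intervals,
    per_suicide_ratios,
)
from selfharm_burden.config import PipelineConfig
from selfharm_burden.costing import combine_costs
from selfharm_burden.incidence import (
    CATCHMENT_AREA_ID,
    estimate_rates,
    extrapolate_incidence,
)


def _mc_inputs(tiny_world, fitted_model, config):
    episodes, model = fitted_model
    pop = tiny_world["population"]
    catchment = pop[pop["area_id"] == CATCHMENT_AREA_ID]
    areas = pop[pop["area_id"] != CATCHMENT_AREA_ID]
    rates = estimate_rates(episodes, catchment, config.age_cap)
    inc = extrapolate_incidence(rates, areas, config.age_cap)
    costs = combine_costs(episodes, model, tiny_world["mff"], config)
    return model, costs, inc, pop


def test_single_cell_aggregation_arithmetic():
    inc = pd.DataFrame({"area_id": ["x"], "age": [30], "gender": ["female"],
                        "expected_presentations": [100.0]})
    means = pd.DataFrame({"age": [30], "gender": ["female"],
                          "mean_cost": [500.0]})
    pop = pd.DataFrame({"area_id": ["x"], "age": [30], "gender": ["female"],
                        "population": [50_000.0]})
    est = aggregate_costs(inc, means, pop)
    assert est["total_cost"].iloc[0] == pytest.approx(50_000.0)
    assert est["cost_per_1000"].iloc[0] == pytest.approx(1000.0)
    assert est["presentations_per_1000"].iloc[0] == pytest.approx(2.0)


def test_national_total_is_sum_of_areas(tiny_world, fitted_model, config):
    model, costs, inc, pop = _mc_inputs(tiny_world, fitted_model, config)
    from selfharm_burden.costing import compute_mean_cost_table
    means = compute_mean_cost_table(
        costs, config, inc[["age", "gender"]].drop_duplicates())
    est = aggregate_costs(inc, means, pop)
    merged = inc.merge(means[["age", "gender", "mean_cost"]],
                       on=["age", "gender"])
    direct = (merged["expected_presentations"] * merged["mean_cost"]).sum()
    assert est["total_cost"].sum() == pytest.approx(direct, rel=1e-12)
    assert (est["cost_male"] + est["cost_female"]).sum() == pytest.approx(
        direct, rel=1e-12)


def test_missing_area_population_raises():
    inc = pd.DataFrame({"area_id": ["ghost"], "age": [30],
                        "gender": ["female"],
                        "expected_presentations": [1.0]})
    means = pd.DataFrame({"age": [30], "gender": ["female"],
                          "mean_cost": [1.0]})
    pop = pd.DataFrame({"area_id": ["x"], "age": [30], "gender": ["female"],
                        "population": [100.0]})
    with pytest.raises(ValueError, match="ghost"):
        aggregate_costs(inc, means, pop)


def test_zero_vcov_collapses_interval(tiny_world, fitted_model, config):
    model, costs, inc, pop = _mc_inputs(tiny_world, fitted_model, config)
    degenerate = model.__class__(
        beta=model.beta,
        vcov=model.vcov * 0.0,
        dispersion=model.dispersion,
        fit_mff=model.fit_mff,
        n_episodes=model.n_episodes,
        n_patients=model.n_patients,
    )
    cfg = config.model_copy(update={"mc_iterations": 200})
    mc, area_ci = monte_carlo_intervals(
        degenerate, costs, inc, pop, tiny_world["mff"], cfg, seed=5)
    assert np.ptp(mc.national_draws) == 0.0
    assert mc.national_ci[0] == pytest.approx(mc.national_point)
    assert mc.national_ci[1] == pytest.approx(mc.national_point)


def test_mc_point_estimate_matches_aggregation(tiny_world, fitted_model,
                                               config):
    """The Monte-Carlo point estimate equals the deterministic aggregate."""
    model, costs, inc, pop = _mc_inputs(tiny_world, fitted_model, config)
    from selfharm_burden.costing import compute_mean_cost_table
    means = compute_mean_cost_table(
        costs, config, inc[["age", "gender"]].drop_duplicates())
    est = aggregate_costs(inc, means, pop)
    cfg = config.model_copy(update={"mc_iterations": 50})
    mc, _ = monte_carlo_intervals(
        model, costs, inc, pop, tiny_world["mff"], cfg, seed=5)
    assert mc.national_point == pytest.approx(est["total_cost"].sum(),
                                              rel=1e-9)


def test_mc_reproducible_and_seed_sensitive(tiny_world, fitted_model,
                                            config):
    model, costs, inc, pop = _mc_inputs(tiny_world, fitted_model, config)
    cfg = config.model_copy(update={"mc_iterations": 400})
    mc1, _ = monte_carlo_intervals(model, costs, inc, pop,
                                   tiny_world["mff"], cfg, seed=5)
    mc2, _ = monte_carlo_intervals(model, costs, inc, pop,
                                   tiny_world["mff"], cfg, seed=5)
    assert mc1.national_ci == mc2.national_ci
    mc3, _ = monte_carlo_intervals(model, costs, inc, pop,
                                   tiny_world["mff"], cfg, seed=6)
    assert mc3.national_ci != mc1.national_ci
    # different seeds agree within Monte-Carlo error
    rel = abs(mc3.national_ci[1] - mc1.national_ci[1]) / mc1.national_ci[1]
    assert rel < 0.02


def test_widening_vcov_never_narrows_interval(tiny_world, fitted_model,
                                              config):
    model, costs, inc, pop = _mc_inputs(tiny_world, fitted_model, config)
    cfg = config.model_copy(update={"mc_iterations": 400})
    widths = []
    for scale in (1.0, 4.0):
        scaled = model.__class__(
            beta=model.beta, vcov=model.vcov * scale,
            dispersion=model.dispersion, fit_mff=model.fit_mff,
            n_episodes=model.n_episodes, n_patients=model.n_patients,
        )
        mc, _ = monte_carlo_intervals(scaled, costs, inc, pop,
                                      tiny_world["mff"], cfg, seed=5)
        widths.append(mc.national_ci[1] - mc.national_ci[0])
    assert widths[1] >= widths[0]


def test_aggregation_linear_in_mean_costs(tiny_world, fitted_model, config):
    """Doubling every mean cost doubles totals and both CI bounds."""
    model, costs, inc, pop = _mc_inputs(tiny_world, fitted_model, config)
    cfg = config.model_copy(update={"mc_iterations": 300})
    mc1, ci1 = monte_carlo_intervals(model, costs, inc, pop,
                                     tiny_world["mff"], cfg, seed=5)
    # doubling all costs: observed doubled, and intercept + log 2
    costs2 = costs.copy()
    costs2["observed_cost"] = costs2["observed_cost"] * 2
    beta2 = model.beta.copy()
    beta2["intercept"] += np.log(2)
    doubled = model.__class__(
        beta=beta2, vcov=model.vcov, dispersion=model.dispersion,
        fit_mff=model.fit_mff, n_episodes=model.n_episodes,
        n_patients=model.n_patients,
    )
    mc2, ci2 = monte_carlo_intervals(doubled, costs2, inc, pop,
                                     tiny_world["mff"], cfg, seed=5)
    assert mc2.national_point == pytest.approx(2 * mc1.national_point)
    assert mc2.national_ci[0] == pytest.approx(2 * mc1.national_ci[0])
    assert mc2.national_ci[1] == pytest.approx(2 * mc1.national_ci[1])


def test_ci_bounds_ordered(tiny_world, fitted_model, config):
    model, costs, inc, pop = _mc_inputs(tiny_world, fitted_model, config)
    cfg = config.model_copy(update={"mc_iterations": 300})
    _, area_ci = monte_carlo_intervals(model, costs, inc, pop,
                                       tiny_world["mff"], cfg, seed=5)
    assert (area_ci["ci_low"] <= area_ci["ci_high"]).all()


def test_non_psd_vcov_projected_with_warning(tiny_world, fitted_model,
                                             config):
    model, costs, inc, pop = _mc_inputs(tiny_world, fitted_model, config)
    bad_vcov = model.vcov.copy()
    # flip the sign of the largest eigenvalue direction
    w, V = np.linalg.eigh(bad_vcov.to_numpy())
    w[-1] = -w[-1]
    bad = (V * w) @ V.T
    broken = model.__class__(
        beta=model.beta,
        vcov=pd.DataFrame(bad, index=model.vcov.index,
                          columns=model.vcov.columns),
        dispersion=model.dispersion, fit_mff=model.fit_mff,
        n_episodes=model.n_episodes, n_patients=model.n_patients,
    )
    cfg = config.model_copy(update={"mc_iterations": 50})
    with pytest.warns(UserWarning, match="PSD"):
        monte_carlo_intervals(broken, costs, inc, pop, tiny_world["mff"],
                              cfg, seed=5)


@pytest.mark.parametrize("total,factor,expected", [
    (128.6e6, 1.04062, 133.8),
    (100e6, 1.05, 105.0),
    (42e6, 1.0, 42.0),
])
def test_inflation(total, factor, expected):
    assert as_million(inflate_to_year(total, factor)) == expected


def test_inflation_rejects_nonpositive_factor():
    with pytest.raises(ValueError):
        inflate_to_year(1.0, 0.0)


def test_per_suicide_ratios_published_arithmetic():
    """Published national totals and 2013 suicide counts reproduce the
    published presentations-per-suicide ratios."""
    episodes = {"male": 0.39 * 228_075, "female": 0.61 * 228_075}
    patients = {"male": 0.39 * 159_857, "female": 0.61 * 159_857}
    suicides = {"male": 3688.0, "female": 1039.0}
    table = per_suicide_ratios(episodes, patients, suicides).set_index(
        ["stratum", "measure"])["ratio"]
    assert table[("total", "episodes")] == 48
    assert table[("male", "episodes")] == 24
    assert table[("total", "patients")] == 34
    assert table[("male", "patients")] == 17


def test_per_suicide_ratio_degenerate_cases():
    table = per_suicide_ratios({"male": 10.0}, {"male": 10.0},
                               {"male": 10.0})
    assert (table["ratio"] == 1).all()
    with pytest.raises(ValueError):
        per_suicide_ratios({"male": 1.0}, {"male": 1.0}, {"male": 0.0})
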