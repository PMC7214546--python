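"""Shared fixtures: small synthetic worlds generated at test time."""

from __future__ import annotations

import pandas as pd
import pytest

from selfharm_burden.config import PipelineConfig
from selfharm_burden.costing import fit_cost_model, impute_assessment_costs
from selfharm_burden.synth import (
    default_truth,
    generate_episodes,
    generate_geography,
)


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig(rng_seed=11)


@pytest.fixture(scope="session")
def tiny_world(config):
    """Small generated world shared across tests (read-only)."""
    truth = default_truth("tiny")
    episodes = generate_episodes(truth, seed=11)
    population, mff, asr, rurality = generate_geography(truth, seed=12)
    return {
        "truth": truth,
        "episodes": episodes,
        "population": population,
        "mff": mff,
        "suicide_asr": asr,
        "rurality": rurality,
    }


@pytest.fixture(scope="session")
def fitted_model(tiny_world, config):
    episodes = impute_assessment_costs(tiny_world["episodes"], config)
    return episodes, fit_cost_model(episodes, config, tiny_world["mff"])


@pytest.fixture()
def episode_frame() -> pd.DataFrame:
    """Three valid hand-written episode records."""
    return pd.DataFrame({
        "episode_id": ["e1", "e2", "e3"],
        "patient_id": ["p1", "p1", "p2"],
        "centre": ["A", "A", "C"],
        "age": [17, 30, 45],
        "gender": ["female", "female", "male"],
        "method": ["poisoning", "injury", "both"],
        "admitted": [True, False, True],
        "assessed": [True, True, False],
        "observed_cost": [500.0, 750.0, None],
        "assessment_cost_included": [False, True, False],
    })
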