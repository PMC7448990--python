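"""Shared fixtures: the default synthetic study at seed 7.

The regulatory-system fixtures are session-scoped because network
inference is the one expensive step; every test that needs the planted
system shares a single realization.
"""

from __future__ import annotations

import numpy as np
import pytest

from matam.enrichment import differential_ranking
from matam.inference import InferenceConfig, build_regulons, infer_network
from matam.signature import log_transform
from matam.simulate import (
    SimulationConfig,
    simulate_pdx_profiles,
    simulate_regulatory_system,
)


@pytest.fixture(scope="session")
def config7() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def system7(config7):
    return simulate_regulatory_system(config7)


@pytest.fixture(scope="session")
def pdx7(config7):
    return simulate_pdx_profiles(config7)


@pytest.fixture(scope="session")
def ranked7(system7):
    labels = system7.annotation.table["condition"].dropna()
    labels = labels[labels.index.str.startswith("TAM")]
    return differential_ranking(log_transform(system7.tam), labels)


@pytest.fixture(scope="session")
def inference_config7() -> InferenceConfig:
    return InferenceConfig(seed=7)


@pytest.fixture(scope="session")
def network7(system7, inference_config7):
    return infer_network(log_transform(system7.cohort), system7.binding,
                         inference_config7)


@pytest.fixture(scope="session")
def regulons7(network7, inference_config7):
    return build_regulons(network7, inference_config7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
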