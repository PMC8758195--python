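"""Shared fixtures: one small rendered population, reused across the suite."""

import numpy as np
import pytest

from eggmatch.features import build_match_graph, extract_features
from eggmatch.imageprep import segment_egg
from eggmatch.synth import ScenarioConfig, generate_population


@pytest.fixture(scope="session")
def population():
    """Six unique hens, four eggs each, one region, no planted links."""
    cfg = ScenarioConfig(
        n_hens=6, clutch_size_range=(4, 4), n_planted_returns=0,
        n_planted_cbp=0, n_planted_renests=0,
        region_labels=("North",), rng_seed=42)
    return generate_population(cfg)


@pytest.fixture(scope="session")
def population_features(population):
    """FeatureSets for every egg of the session population."""
    out = []
    for egg in population.eggs:
        mask = segment_egg(egg.image)
        out.append(extract_features(egg.image, mask))
    return out


@pytest.fixture(scope="session")
def population_graph(population_features):
    return build_match_graph(population_features, batch_label="all")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
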