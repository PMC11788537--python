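"""Shared fixtures: small seeded synthetic scenarios and cached study-scale
pipeline products (generated once per session, reused across tests)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from snowphen import PhenologyGAM, SyntheticConfig, generate_dataset, metrics_table

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

SMALL = SyntheticConfig(
    years=(2014, 2015),
    regions=("northern", "southern"),
    temp_region_offsets=(-1.0, 1.5),
    melt50_region_offsets=(6.0, -8.0),
    n_obs_per_region_year=150,
)


@pytest.fixture(scope="session")
def small_dataset():
    """2 years x 2 regions x 150 obs: fast end-to-end surface."""
    return generate_dataset(SMALL, seed=7)


@pytest.fixture(scope="session")
def study_dataset():
    """Full study scale: 16 years x 4 regions x 200 obs/region-year."""
    return generate_dataset(seed=0)


@pytest.fixture(scope="session")
def study_curves(study_dataset):
    """Phenology curves for every year x region at study scale."""
    curves = []
    for year, grp in study_dataset.observations.groupby("year"):
        res = PhenologyGAM(grp, int(year)).fit(seed=int(year))
        curves.extend(res.curves().values())
    return curves


@pytest.fixture(scope="session")
def study_metrics(study_curves):
    return metrics_table(study_curves)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
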