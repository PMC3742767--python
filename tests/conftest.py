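import dataclasses

import numpy as np
import pytest

from seabirdmsp.config import SimulationConfig
from seabirdmsp.region import StudyRegion, default_region
from seabirdmsp import survey_prep
from seabirdmsp.synthetic_data import simulate_dataset


@pytest.fixture(scope="session")
def region():
    return default_region()


@pytest.fixture(scope="session")
def small_region(region):
    """Same geography, but only the first six cruises (two years)."""
    return StudyRegion(
        boundary=region.boundary, colony=region.colony,
        mainland=region.mainland, isobath_200m=region.isobath_200m,
        calendar=region.calendar[:6],
    )


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def dataset_small(config, small_region):
    return simulate_dataset(config, small_region)


@pytest.fixture(scope="session")
def model_table_small(config, small_region, dataset_small):
    ds = dataset_small
    table, report = survey_prep.build_model_table(
        ds.effort, ds.segments, ds.sightings, ds.ctd,
        ds.monthly_indices, ds.daily_upwelling, small_region,
        species=list(config.species))
    return table


@pytest.fixture(scope="session")
def dataset_full(config, region):
    """All 27 cruises; reused by the bookkeeping-heavy tests."""
    return simulate_dataset(config, region)


@pytest.fixture(scope="session")
def model_table_full(config, region, dataset_full):
    ds = dataset_full
    table, _ = survey_prep.build_model_table(
        ds.effort, ds.segments, ds.sightings, ds.ctd,
        ds.monthly_indices, ds.daily_upwelling, region,
        species=list(config.species))
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_config(**over) -> SimulationConfig:
    return dataclasses.replace(SimulationConfig(seed=5), **over)
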