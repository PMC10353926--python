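import numpy as np
import pytest

from heatmort.first_stage import ModelConfig, fit_all_regions
from heatmort.synthetic import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """4 countries x 3 regions, 6 years of weeks: enough signal to fit."""
    cfg = SimConfig(
        n_countries=4, regions_per_country=3, year_start=2015, year_end=2020, seed=42
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def fitted_small(small_dataset):
    """First-stage reduced associations of the small dataset."""
    reduced, excluded = fit_all_regions(
        small_dataset.weekly, small_dataset.regions, ModelConfig()
    )
    assert not excluded
    return reduced


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
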