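import numpy as np
import pytest

from cichlidhab.census import load_species_metadata
from cichlidhab.synth import ScenarioConfig, SpeciesNiche, generate_scenario


@pytest.fixture(scope="session")
def metadata():
    return load_species_metadata()


@pytest.fixture(scope="session")
def small_config():
    """A reduced scenario (smaller grid, fewer years) for fast pipeline tests."""
    return ScenarioConfig(
        n_rows=16,
        n_cols=6,
        slope_per_row=0.6,
        n_years=5,
        master_seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, small_config):
    from cichlidhab.pipeline import run_simulate

    out = tmp_path_factory.mktemp("dataset")
    run_simulate(small_config, out)
    return out


@pytest.fixture(scope="session")
def default_scenario():
    return generate_scenario(ScenarioConfig(master_seed=5))


def two_species_config(seed, mu_a=3.0, mu_b=10.0, sigma=0.8):
    """Two well-separated depth specialists on the default quadrat."""
    species = [
        SpeciesNiche("Aaa", "grazer", "territorial", mu_a, sigma, 0.0),
        SpeciesNiche("Bbb", "grazer", "territorial", mu_b, sigma, 0.0),
    ]
    return ScenarioConfig(master_seed=seed, species=species)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
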