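import pytest

from phenoscreen import ScreeningConfig, generate_growth_series, generate_population


@pytest.fixture(scope="session")
def default_config() -> ScreeningConfig:
    return ScreeningConfig(seed=1)


@pytest.fixture(scope="session")
def default_population(default_config):
    """One default-scale synthetic trial: (config, phenotypes, truth)."""
    phenotypes, truth = generate_population(default_config)
    return default_config, phenotypes, truth


@pytest.fixture(scope="session")
def default_growth(default_population):
    """Growth series + true generating parameters for the default trial."""
    config, _, truth = default_population
    series, params = generate_growth_series(config, truth)
    return series, params
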