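import pytest

from ohcm_burden import GeneratorConfig, generate_population, resources


@pytest.fixture(scope="session")
def codelists():
    return resources.default_codelists()


@pytest.fixture(scope="session")
def drug_map():
    return resources.default_drug_map()


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic population reused by cross-module tests."""
    return generate_population(GeneratorConfig(n_patients=120, seed=7))
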