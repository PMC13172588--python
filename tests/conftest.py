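import pytest

from ribopp.synthetic_data import SimConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """Full synthetic study at the default configuration (seed 1)."""
    return generate_study(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """Reduced study for fast structural tests."""
    return SimConfig(
        n_genes=300,
        mean_length=200,
        n_metabolites=30,
        metastasis_size=60,
        pathway_size=25,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)
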