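import pytest

from essnet import SimulationConfig, generate


SMALL_CONFIG = dict(
    n_mouse_genes=400,
    n_diseases=60,
    n_classes=5,
    n_patients=5000,
    n_rr_pairs=5,
    ppi_n_proteins=600,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Scaled-down planted configuration shared by the unit tests."""
    return SimulationConfig(seed=11, **SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate(small_config)
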