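from datetime import datetime

import pytest
from hypothesis import settings

from pgxbridge import default_config, generate_toy_panel_tables, simulate_plate
from pgxbridge.hl7 import default_mapping

settings.register_profile("deterministic", derandomize=True, max_examples=100)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy_config():
    """Two-gene toy panel: CYP2C19 (plain metabolizer wording) and CYP2D6
    (activity scores), two assays each."""
    return default_config(n_genes=2, n_samples=12, seed=7)


@pytest.fixture(scope="session")
def toy_tables(toy_config):
    return generate_toy_panel_tables(toy_config)


@pytest.fixture(scope="session")
def toy_plate(toy_config):
    return simulate_plate(toy_config)


@pytest.fixture(scope="session")
def toy_mapping(toy_tables):
    return default_mapping(toy_tables.panel_genes)


@pytest.fixture()
def fixed_clock():
    return lambda: datetime(2024, 3, 1, 12, 0, 0)
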