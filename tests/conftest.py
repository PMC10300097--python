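import pytest

from tubuvolt import ElectrodeConfig, MCConfig, PhysicalConstants
from tubuvolt.synthetic import paper_fixture_tables


@pytest.fixture(scope="session")
def consts() -> PhysicalConstants:
    return PhysicalConstants()


@pytest.fixture(scope="session")
def electrode() -> ElectrodeConfig:
    return ElectrodeConfig()


@pytest.fixture(scope="session")
def fixtures():
    """Embedded published reference tables (single source of those numbers)."""
    return paper_fixture_tables()


@pytest.fixture()
def mc_config() -> MCConfig:
    return MCConfig(rng_seed=1234)
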