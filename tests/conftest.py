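import pytest

from foodlca import generate_bundle, table1_fixture


@pytest.fixture(scope="session")
def bundle():
    """Default-size synthetic bundle (12 countries, 3 continents, 40 foods)."""
    return generate_bundle(seed=42)


@pytest.fixture(scope="session")
def fixture_bundle():
    """Two-country apricot bundle mirroring the worked consumption example."""
    return table1_fixture()
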