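import pytest

from topoconv.fixtures import TOY_SYSTEM_NAMES, generate_toy_system


@pytest.fixture(scope="session")
def toy_systems():
    """All four standard toy systems with their serialised texts, built once."""
    return {name: generate_toy_system(name) for name in TOY_SYSTEM_NAMES}


@pytest.fixture(scope="session")
def chain4(toy_systems):
    return toy_systems["chain4"][0]


@pytest.fixture(scope="session")
def methane(toy_systems):
    return toy_systems["methane"][0]


@pytest.fixture(scope="session")
def water(toy_systems):
    return toy_systems["water_tip3p"][0]


@pytest.fixture(scope="session")
def ring6(toy_systems):
    return toy_systems["ring6"][0]
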