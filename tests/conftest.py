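import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cmlsemantics.dictionary import default_dictionary_registry
from cmlsemantics.fixtures import paper_fixtures
from cmlsemantics.refs import default_catalog
from cmlsemantics.units import default_units_registry


@pytest.fixture(scope="session")
def fixtures():
    return paper_fixtures()


@pytest.fixture()
def dummy_dictionary(fixtures):
    # mutated by some tests: hand out a fresh copy
    return fixtures.dummy_dictionary.deep_copy()


@pytest.fixture()
def polymer_fragment(fixtures):
    return fixtures.polymer_fragment.deep_copy()


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def units_registry():
    return default_units_registry()


@pytest.fixture(scope="session")
def dict_registry():
    return default_dictionary_registry()
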