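import pytest

from ulicees.fixtures import load_fixtures
from ulicees.types import GwpSet


@pytest.fixture(scope="session")
def tables():
    return load_fixtures()


@pytest.fixture(scope="session")
def gwp():
    return GwpSet()
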