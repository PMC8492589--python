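import pytest

from scmetox.compounds import get_compound
from scmetox.rules import default_catalog


@pytest.fixture(scope="session")
def jwh200():
    return get_compound("JWH-200")


@pytest.fixture(scope="session")
def a796260():
    return get_compound("A-796260")


@pytest.fixture(scope="session")
def emb_pinaca():
    return get_compound("5F-EMB-PINACA")


@pytest.fixture(scope="session")
def morpholine_catalog():
    return default_catalog("morpholinoethyl-indole")


@pytest.fixture(scope="session")
def indazole_catalog():
    return default_catalog("indazole-carboxamide-ester")
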