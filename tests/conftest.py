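import pytest

from tessera.codes import load_code
from tessera.tesserae import generate_tesserae, tessera_oligos


@pytest.fixture(scope="session")
def tesserae():
    return generate_tesserae()


@pytest.fixture(scope="session")
def tessera_set():
    return tessera_oligos()


@pytest.fixture(scope="session")
def mito_code():
    return load_code(2)


@pytest.fixture(scope="session")
def euplotid_code():
    return load_code(10)
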