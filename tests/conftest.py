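import pytest

from utrvar import generate_fixture, pkd1_like_model


@pytest.fixture(scope="session")
def fixture_pair():
    return generate_fixture(seed=1)


@pytest.fixture(scope="session")
def fixture_utr(fixture_pair):
    return fixture_pair[0]


@pytest.fixture(scope="session")
def model():
    return pkd1_like_model()
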