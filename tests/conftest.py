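import pytest

from healthlit import PrepConfig, fixture_lexicons


@pytest.fixture(scope="session")
def flex():
    """Fixture lexicon set consistent with the synthetic-text generator."""
    return fixture_lexicons()


@pytest.fixture()
def cfg():
    return PrepConfig()
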