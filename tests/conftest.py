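import pytest

from korero import fixtures


@pytest.fixture()
def demo_graph():
    return fixtures.build_demo_graph()


@pytest.fixture(scope="session")
def registry():
    return fixtures.default_intents()


@pytest.fixture(scope="session")
def lexicon():
    return fixtures.default_risk_lexicon()


@pytest.fixture()
def coverage_script():
    return fixtures.coverage_script()
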