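import pytest

from gocc.fixtures import CASE_IDS, fixture_resources, load_fixture


@pytest.fixture(scope="session")
def resources():
    return fixture_resources()


@pytest.fixture(scope="session")
def loc_dict(resources):
    return resources[0]


@pytest.fixture(scope="session")
def cx_dict(resources):
    return resources[1]


@pytest.fixture(scope="session")
def lexicon(resources):
    return resources[2]


@pytest.fixture(scope="session")
def cases():
    """All shipped worked-example cases, keyed by id."""
    return {cid: load_fixture(cid) for cid in CASE_IDS}
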