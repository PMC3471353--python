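import io

import pytest

from sparql_complete.fixtures import walkthrough_fixture
from sparql_complete.index import TermIndex, load_json_index


@pytest.fixture(scope="session")
def walkthrough():
    return walkthrough_fixture()


@pytest.fixture(scope="session")
def wt_index(walkthrough) -> TermIndex:
    """English walkthrough index (properties, KEGG individual, namespaces)."""
    return walkthrough.build_index()


@pytest.fixture(scope="session")
def wt_index_de(walkthrough) -> TermIndex:
    """Walkthrough index with the German label extension merged in."""
    return walkthrough.build_index(german=True)


@pytest.fixture()
def engine(walkthrough):
    return walkthrough.engine()


@pytest.fixture()
def engine_noreg(walkthrough):
    return walkthrough.engine(registry=False)


def index_of(turtle: str) -> TermIndex:
    index = TermIndex()
    index.index_ontology(io.StringIO(turtle), fmt="turtle")
    return index
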