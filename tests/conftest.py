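import pytest

from psicquic_lite.fixtures import CANONICAL_SPEC, FixtureSpec, generate
from psicquic_lite.query_engine import build_index


@pytest.fixture(scope="session")
def canonical():
    """The canonical 500-record 2.7 collection with its answer key."""
    return generate(CANONICAL_SPEC)


@pytest.fixture(scope="session")
def canonical_records(canonical):
    return canonical[0]


@pytest.fixture(scope="session")
def canonical_key(canonical):
    return canonical[1]


@pytest.fixture(scope="session")
def canonical_index(canonical_records):
    return build_index(canonical_records, dialect="2.7")


@pytest.fixture(scope="session")
def small_collection():
    """A quick 60-record collection for I/O and REST tests."""
    return generate(FixtureSpec(n_records=60, seed=7))
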