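import pytest

from hookahrisk import (
    load_study_meta,
    load_study_tables,
    load_toxicity_fixture,
)


@pytest.fixture(scope="session")
def study_table():
    """The bundled 5-tobacco x 29-element x 3-compartment study table."""
    return load_study_tables()


@pytest.fixture(scope="session")
def study_meta():
    return load_study_meta()


@pytest.fixture(scope="session")
def toxrefs():
    return load_toxicity_fixture()
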