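import pytest

from triomic.fixtures import (
    load_fixture_kb,
    load_fixture_phenotype,
    load_fixture_tables,
    load_printed_counts,
)


@pytest.fixture(scope="session")
def fixture_tables():
    return load_fixture_tables()


@pytest.fixture(scope="session")
def fixture_kb():
    return load_fixture_kb()


@pytest.fixture(scope="session")
def fixture_phenotype():
    return load_fixture_phenotype()


@pytest.fixture(scope="session")
def printed_counts():
    return load_printed_counts()


@pytest.fixture(scope="session")
def fixture_result(fixture_tables, fixture_kb, fixture_phenotype):
    """One full pipeline run on the bundled worked example, shared across tests."""
    from triomic.pipeline import run_integration

    genes, proteins, metabolites = fixture_tables
    return run_integration(genes, proteins, metabolites, fixture_kb, phenotype=fixture_phenotype)
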