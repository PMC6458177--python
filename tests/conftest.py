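import pytest

from mammodose import CohortParams, generate_cohort, load_factor_tables


@pytest.fixture(scope="session")
def tables():
    return load_factor_tables("default")


@pytest.fixture(scope="session")
def small_cohort(tables):
    """A 400-exposure synthetic cohort shared across tests."""
    records, sidecar = generate_cohort(CohortParams(n=400, seed=11), tables=tables)
    return records, sidecar
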