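import pytest

from thermogroups import load_all_tables, reference_library


@pytest.fixture(scope="session")
def tables():
    return load_all_tables()


@pytest.fixture(scope="session")
def library(tables):
    return reference_library(tables)
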