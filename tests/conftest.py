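import pytest

from detoxevol import default_species_tree, load_study_fixture


@pytest.fixture(scope="session")
def species_tree():
    return default_species_tree()


@pytest.fixture(scope="session")
def table1():
    return load_study_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return load_study_fixture("table2")
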