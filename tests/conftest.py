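import pytest

from triokit import datasets


@pytest.fixture(scope="session")
def trio_gene():
    return datasets.load_trio_gene_model()


@pytest.fixture(scope="session")
def trio_mutations():
    return datasets.load_trio_mutations()


@pytest.fixture(scope="session")
def expected_tally():
    return datasets.load_expected_tally()


@pytest.fixture(scope="session")
def ddg_records():
    return datasets.load_ddg_table()


@pytest.fixture(scope="session")
def toy_structure():
    return datasets.toy_structure_path()
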