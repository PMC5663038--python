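import numpy as np
import pytest

from epiconcord import concordance, synthdata


@pytest.fixture(scope="session")
def table1_records():
    return synthdata.table1_fixture()


@pytest.fixture(scope="session")
def table1_k27(table1_records):
    return concordance.tabulate_patterns(table1_records, "H3K27me3")


@pytest.fixture(scope="session")
def table1_k4(table1_records):
    return concordance.tabulate_patterns(table1_records, "H3K4me3")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
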