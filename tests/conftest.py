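import pytest

from herbqc.fixtures import load_fixture
from herbqc.synthetic_data import default_design, sample_contents

ANALYTES = ["chlorogenic_acid", "caffeic_acid", "p_coumaric_acid", "luteolin", "apigenin"]


@pytest.fixture(scope="session")
def design():
    """Default study design with its default noise model."""
    return default_design(1)


@pytest.fixture(scope="session")
def clean_design(design):
    """Same design, zero detector noise and zero baseline drift."""
    return design.noiseless()


@pytest.fixture(scope="session")
def contents(design):
    return sample_contents(design, 15, 1)


@pytest.fixture(scope="session")
def table6():
    return load_fixture("table6_contents").set_index("batch")


@pytest.fixture(scope="session")
def table5():
    return load_fixture("table5_rcf")
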