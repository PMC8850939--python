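import pytest

from gcsf_cea.lifetable import make_life_table
from gcsf_cea.params import ParameterSet


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture(scope="session")
def life_table():
    return make_life_table()
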