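import numpy as np
import pytest

from oeot import GasSchedule, load_extinction_table
from oeot.phantom import DEFAULT_WAVELENGTHS


@pytest.fixture(scope="session")
def ext_table():
    return load_extinction_table()


@pytest.fixture(scope="session")
def wavelengths15():
    return np.asarray(DEFAULT_WAVELENGTHS)


@pytest.fixture(scope="session")
def schedule():
    return GasSchedule.default_challenge()
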