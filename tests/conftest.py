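import numpy as np
import pytest

from osteograft import load_builtin
from osteograft.dataset import design_matrix


@pytest.fixture(scope="session")
def builtin():
    return load_builtin()


@pytest.fixture(scope="session")
def builtin_nominal():
    return load_builtin("nominal")


@pytest.fixture(scope="session")
def scenario_a_design(builtin):
    """The all-seven-materials design: CaCO3 wt%, Ti wt%, macroporosity → BMC."""
    return design_matrix(builtin, ("caco3_wt", "ti_wt", "macroporosity"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
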