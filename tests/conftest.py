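import numpy as np
import pytest

from neuromotor import fixtures as fx
from neuromotor.cell_models import builtin_template


@pytest.fixture(scope="session")
def ankle_tables():
    return fx.ankle_l4l5_tables(scale=1.0)


@pytest.fixture(scope="session")
def ankle_tables_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("tables")
    fx.write_ankle_l4l5(out, scale=1.0)
    return out


@pytest.fixture(scope="session")
def small_model():
    """Scaled-down ankle circuit, realized with a fixed seed."""
    return fx.ankle_l4l5_model(seed=1, scale=0.1)


@pytest.fixture(scope="session")
def slow_template():
    return builtin_template("M_cell_Slow")


@pytest.fixture(scope="session")
def if_template():
    return builtin_template("interneuron_if")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
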