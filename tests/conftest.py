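import pytest
from hypothesis import HealthCheck, settings

from rqscreen.datasets import load_table1
from rqscreen.markers import default_panel
from rqscreen.synthetic_data import make_reference_set

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def references():
    return make_reference_set(seed=11)


@pytest.fixture(scope="session")
def panel(references):
    return default_panel(references)


@pytest.fixture(scope="session")
def matrix_panel():
    """Panel without reference sequences (matrix-only use)."""
    return default_panel()


@pytest.fixture(scope="session")
def table1():
    return load_table1()
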