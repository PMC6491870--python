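import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from delbin.stock_panel import load_cs_group7_matrix, load_cs_group7_registry

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cs_panel():
    """The packaged Chinese Spring group-7 Dt/Del stock registry."""
    return load_cs_group7_registry()


@pytest.fixture(scope="session")
def cs_matrix(cs_panel):
    """The packaged P1-P6 amplification matrix over the group-7 panel."""
    return load_cs_group7_matrix(cs_panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(20190523)
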