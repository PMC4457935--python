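import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def region():
    from evoselect.reference import default_region

    return default_region()


@pytest.fixture(scope="session")
def scheme():
    from evoselect.library_model import DopingScheme

    return DopingScheme.default()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
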