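import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scheme():
    from puredisplay.synthetic_data import default_library_scheme

    return default_library_scheme(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
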