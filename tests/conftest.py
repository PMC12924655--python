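import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def calibrated_baseline():
    """Single-strain gLV fixture calibrated to a 6.5 h pathogen extinction."""
    from probisim import glv

    return glv.calibrate_single_strain(6.5)


@pytest.fixture(scope="session")
def small_grid():
    from probisim import abm

    return abm.GridConfig(width=30, height=30,
                          seed_layout={"A": 40, "B": 60, "C": 40, "P": 30})


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
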