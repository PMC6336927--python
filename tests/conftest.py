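import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cortexgrid import ModuleSet

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ms_default():
    """Literature-convention set: 6 modules, geometric scales, 5x5 bins."""
    return ModuleSet.default()


@pytest.fixture
def ms_int():
    """Integer-tuned set used by learning/recognition tests: unit moves shift
    phases by whole bins."""
    return ModuleSet.integer_tuned()
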