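import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sitsim as s

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wild_cube():
    return s.build_cube("wild")


@pytest.fixture(scope="session")
def calibrated_small(wild_cube):
    """Calibrated life history + equilibrium at a small population."""
    lh = s.default_life_history(n_female_eq=500.0)
    return s.calibrate_equilibrium(lh, wild_cube)


@pytest.fixture(scope="session")
def calibrated_default(wild_cube):
    lh = s.default_life_history()
    return s.calibrate_equilibrium(lh, wild_cube)


def seedseq(*key):
    return np.random.SeedSequence(list(key))
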