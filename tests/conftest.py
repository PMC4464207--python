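import numpy as np
import pytest
from hypothesis import settings

from lipotrap import RateParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def jam_params() -> RateParams:
    """The rate pair whose occupancy exponent is the fitted value 2.3."""
    return RateParams(r0=1.3, lam=1.0)


@pytest.fixture
def fine_grid() -> np.ndarray:
    return np.linspace(0.0, 10.0, 2001)
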