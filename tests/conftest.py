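import numpy as np
import pytest

from avsync import NetworkParams


@pytest.fixture
def theta_params():
    """Theta-band network: intrinsic frequencies (3, 4, 5), balanced kappa=5."""
    def make(tau: float, lag_sign: str = "visual_leads", kappa: float = 5.0):
        return NetworkParams(3.0, 4.0, 5.0, kappa, kappa, tau, lag_sign)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20160809)
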