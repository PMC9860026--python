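import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from megre.experiments import calibrated_sigma0
from megre.protocol import train_from_params
from megre.signal_model import TissueParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def roi3_tissue():
    """The T2* = 69 ms / T1 = 878 ms reference region."""
    return TissueParams(m0=1.0, t1=878.0, t2_star=69.0)


@pytest.fixture(scope="session")
def mono_train():
    """Monopolar full-range train: TE1 3.84 ms, spacing 2.92 ms, 32 echoes."""
    return train_from_params(3.84, 2.92, "monopolar", te_max=97.0)


@pytest.fixture(scope="session")
def bip_train():
    """Bipolar full-range train: TE1 3.84 ms, spacing 1.47 ms, 64 echoes."""
    return train_from_params(3.84, 1.47, "bipolar", te_max=97.0)


@pytest.fixture(scope="session")
def sigma0():
    """Calibrated reference noise level (computed once per session)."""
    return calibrated_sigma0()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
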