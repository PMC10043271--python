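import numpy as np
import pytest

from poregel.params import GelParams, preset


@pytest.fixture(scope="session")
def anchor():
    """The actin-liposome preset (the field-solver calibration anchor)."""
    return preset("actin_liposome")


@pytest.fixture(scope="session")
def simple_params():
    """Hand-checkable parameter set used by the worked numeric examples."""
    return GelParams(eta=1000.0, Gamma=1e14, sigma0=1.0, zeta=0.0,
                     tau_a=100.0, gamma=1e-4, f_adh=1e7, R_L=1e-5, d=1e-7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230915)
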