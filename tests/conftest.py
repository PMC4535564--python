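import numpy as np
import pytest

from oculomech.constitutive import (CORNEA_PARAMS, SCLERA_PARAMS,
                                    DeformationHistory, MaterialParams)
from oculomech.tensile import SCLERA_STRIP, LoadingProtocol


@pytest.fixture
def sclera():
    return SCLERA_PARAMS


@pytest.fixture
def cornea():
    return CORNEA_PARAMS


@pytest.fixture
def simple_params():
    """alpha=2, mu=1 MPa: the hand-checkable material."""
    return MaterialParams(alpha=2.0, mu=1.0, beta=1.0, g_visc=0.0)


@pytest.fixture
def ramp_history():
    """Constant strain-rate ramp: rate 0.01/s for 100 s (engineering strain)."""
    t = np.linspace(0.0, 100.0, 2001)
    return DeformationHistory(time=t, stretch=1.0 + 0.01 * t)
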