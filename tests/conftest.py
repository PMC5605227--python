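import numpy as np
import pytest

from cyanoclock.phasemodel import OscillatorParams
from cyanoclock.stepresponse import LinearStepParams
from cyanoclock.synth import GroundTruth

# anchors follow the entrained-phase centers of the linearization windows:
# dawn responses centered on CT 2 (18-34 CT window), dusk on CT 14 (6-22)
ANCHOR_L = 1.0 / 12.0
ANCHOR_D = 7.0 / 12.0


def linear_steps(l=0.34, d=0.38):
    L = LinearStepParams(kind="dawn", slope=l, anchor=ANCHOR_L,
                         breakpoint=ANCHOR_L + 0.5)
    D = LinearStepParams(kind="dusk", slope=d, anchor=ANCHOR_D,
                         breakpoint=ANCHOR_D - 0.5)
    return L, D


@pytest.fixture
def kai_params():
    """Measured-type free-running periods (light 23.7 h, dark 25.7 h)."""
    return OscillatorParams(T_day=23.7, T_night=25.7)


@pytest.fixture
def measured_steps():
    """Linear L/D with the polarization-derived slopes."""
    return linear_steps()


@pytest.fixture
def linear_truth(kai_params):
    L, D = linear_steps(l=0.4, d=0.4)
    return GroundTruth(params=kai_params, L=L, D=D, noise_sigma=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
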