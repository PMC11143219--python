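import numpy as np
import pytest

from nafpatlak.frames import TimeActivityCurve, schedule_60min, schedule_90min
from nafpatlak.simulate import DEFAULT_IDIF, feng_fine_curve, frame_average


@pytest.fixture(scope="session")
def s60():
    return schedule_60min()


@pytest.fixture(scope="session")
def s90():
    return schedule_90min()


@pytest.fixture(scope="session")
def fine_idif(s60):
    """Default bolus input sampled on the fine grid of the 60-min protocol."""
    return feng_fine_curve(DEFAULT_IDIF, s60)


@pytest.fixture(scope="session")
def idif_tac(s60, fine_idif):
    """Frame-averaged blood TAC of the default bolus."""
    return TimeActivityCurve(s60, frame_average(fine_idif, s60), "aorta_IDIF")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240531)
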