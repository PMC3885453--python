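import numpy as np
import pytest

from rrtmodels import (
    DoubleResponseDesign,
    HuangDesign,
    Population,
    Scrambler,
    ThreeStageParams,
    TwoSampleDesign,
)


@pytest.fixture
def pop():
    return Population(10.0, 4.0, "gamma")


@pytest.fixture
def params():
    return ThreeStageParams(0.3, 0.1, 0.5)  # A = 0.1 + 0.6*0.5 = 0.4


@pytest.fixture
def scr_pair():
    return Scrambler(2.0, 1.0), Scrambler(4.0, 1.0)


@pytest.fixture
def split_design(scr_pair):
    return TwoSampleDesign(*scr_pair, -1, 200, 200)


@pytest.fixture
def mehta_design(scr_pair):
    return TwoSampleDesign(*scr_pair, +1, 200, 200)


@pytest.fixture
def double_design(scr_pair):
    return DoubleResponseDesign(*scr_pair, 200)


@pytest.fixture
def huang_design(scr_pair):
    mult = Scrambler(1.0, 0.25)
    return HuangDesign(mult, scr_pair[0], mult, scr_pair[1], 200, 200)


def mc_tol(var, reps, nse=4.0):
    """Half-width of an nse-standard-error Monte Carlo band for a mean."""
    return nse * np.sqrt(var / reps)
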