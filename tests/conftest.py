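import numpy as np
import pytest

from petkin import FrameSchedule, ModelSpec, simulate_tissue
from petkin.kinetics import KineticParams
from petkin.synthetic import SyntheticTruth, make_aif

#: Median lesion rate constants of the irreversible two-tissue model.
LESION_PARAMS = KineticParams(K1=0.136, k2=0.277, k3=0.108)


@pytest.fixture(scope="session")
def truth():
    return SyntheticTruth(seed=0)


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default_60min()


@pytest.fixture(scope="session")
def blood_data(truth):
    """(plasma, whole_blood, sampler, manual_samples) for the default truth."""
    return make_aif(truth)


@pytest.fixture(scope="session")
def plasma(blood_data):
    return blood_data[0]


@pytest.fixture(scope="session")
def whole_blood(blood_data):
    return blood_data[1]


@pytest.fixture(scope="session")
def muscle_tac(plasma, whole_blood, schedule):
    """Noiseless muscle TAC (low uptake) for phantom backgrounds."""
    p = KineticParams(K1=0.027, k2=0.29, k3=0.038)
    return simulate_tissue(ModelSpec("2T3k"), p, plasma, whole_blood, schedule,
                           region_label="muscle")


@pytest.fixture(scope="session")
def lesion_tac(plasma, whole_blood, schedule):
    """Noiseless lesion TAC from the median irreversible-model parameters."""
    return simulate_tissue(
        ModelSpec("2T3k"), LESION_PARAMS, plasma, whole_blood, schedule,
        region_label="lesion",
    )
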