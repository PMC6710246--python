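import numpy as np
import pytest

from batquant import kinetics, synthio


@pytest.fixture(scope="session")
def schedule():
    return kinetics.FrameSchedule.default()


@pytest.fixture(scope="session")
def cp(schedule):
    """Default Feng-type plasma input on the fine grid."""
    return synthio.make_input_function(schedule=schedule)


@pytest.fixture(scope="session")
def basis(cp, schedule):
    return kinetics.build_basis(cp, schedule)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
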