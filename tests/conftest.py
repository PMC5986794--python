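import numpy as np
import pytest

from myopsych import EMGConfig, SubjectModel
from myopsych.emg import design_filter_chain
from myopsych.strategies import StrategyConfig
from myopsych.task import TargetLayout


@pytest.fixture
def subject():
    return SubjectModel(rng_seed=42)


@pytest.fixture
def noiseless_subject():
    return SubjectModel(sigma_sens=0.0, sigma_cntl=0.0, motor_noise=0.0,
                        adaptation_gain=1.0, rng_seed=0)


@pytest.fixture
def emg_config():
    return EMGConfig()


@pytest.fixture
def chain():
    return design_filter_chain(1000.0)


@pytest.fixture
def layout():
    return TargetLayout()


@pytest.fixture(params=["RAW", "FLT", "AUG"])
def strategy(request):
    return StrategyConfig(name=request.param)
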