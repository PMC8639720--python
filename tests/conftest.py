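import numpy as np
import pytest
from hypothesis import settings

from thermovir import Briere1Params, Logan1Params
from thermovir import fitting, synthdata

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def icipe20_logan1() -> Logan1Params:
    """Published Logan-1 parameter set for a highly virulent isolate."""
    return Logan1Params(y0=0.14, p=0.07, v=1.66, t_max=33.27)


@pytest.fixture
def briere_truth() -> Briere1Params:
    return Briere1Params(n=1.3e-4, t_min=8.0, t_max=35.2)


@pytest.fixture
def noiseless_growth(briere_truth) -> fitting.ResponseDataset:
    design = synthdata.SimulationDesign(noise_sd=0.0, seed=11)
    return synthdata.simulate_growth(design, briere_truth)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
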