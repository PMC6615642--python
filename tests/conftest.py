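import numpy as np
import pytest

from mitoctrl.dynamics import LinearLaw, PopulationState
from mitoctrl.treatment import TreatmentParams

# fitted treatment operating point used across the suite
MAP = {"I0": 122.82, "b": 46.68, "c1": 1.90e-4, "xi": 0.72, "delta": 1.26}


@pytest.fixture
def linear_law():
    """Reference linear control: mu=0.07/d, Var floor mu/c1 = 100."""
    return LinearLaw(mu=0.07, c1=7e-4, w_opt=1000.0, delta=0.5)


@pytest.fixture
def map_law():
    return LinearLaw(mu=0.07, c1=MAP["c1"],
                     w_opt=180.0 + MAP["delta"] * 720.0, delta=MAP["delta"])


@pytest.fixture
def map_treatment():
    return TreatmentParams(I0=MAP["I0"], b=MAP["b"], xi=MAP["xi"], n_rounds=4)


@pytest.fixture
def map_init():
    return PopulationState(180.0, 720.0)
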