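import numpy as np
import pytest
from hypothesis import settings

from triadkit import SimulationDesign, fit_rasch, simulate_responses

settings.register_profile("default", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("default")

STUDY_SEED = 101


@pytest.fixture(scope="session")
def study_calibration():
    """A full study-scale calibration: 197 respondents x 225 items.

    Simulated at the scale of a realistic triad-bank norming sample
    (abilities N(0,1), difficulties uniform on [-3.8, 1.7]) and fitted
    once; shared by recovery, agreement and subset tests.
    """
    design = SimulationDesign(n_respondents=197, n_items=225, seed=STUDY_SEED)
    sim = simulate_responses(design)
    bank, abilities, stats = fit_rasch(sim.responses)
    return sim, bank, abilities, stats


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
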