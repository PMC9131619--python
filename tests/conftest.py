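import numpy as np
import pandas as pd
import pytest

import pitsval as pv
from pitsval.models import ChoiceData
from pitsval.simulate import SyntheticTruth, sample_respondents, simulate_observations


@pytest.fixture(scope="session")
def small_study():
    """A small mixed study (24 respondents, 2 taste x 2 scale classes)."""
    cfg = pv.StudyConfig(n_respondents=24, n_click_through=0, seed=42)
    choices, cov, truth = pv.generate_study(cfg)
    obs = pv.observations_from_frame(choices)
    clean, log = pv.apply_cleaning(obs)
    return {"choices": choices, "covariates": cov, "truth": truth,
            "observations": clean, "data": ChoiceData(clean), "cleaning": log}


def homogeneous_truth(gamma=None) -> SyntheticTruth:
    """Single taste class (the value-set class), single scale class."""
    base = SyntheticTruth()
    return SyntheticTruth(
        taste_betas=[base.taste_betas[0]],
        etas=base.etas,
        gamma=np.zeros(4) if gamma is None else np.asarray(gamma, float),
        scale_factors=np.array([1.0]),
    )


def simulate_homogeneous(n: int, seed: int, gamma=None):
    """Observations from a homogeneous (no-heterogeneity) study."""
    truth = homogeneous_truth(gamma)
    resp = sample_respondents(n, seed)
    labels = np.zeros(n, dtype=int)
    obs = simulate_observations(resp, labels, labels, truth, seed + 1)
    return obs, resp, truth


@pytest.fixture(scope="session")
def homoskedastic_study():
    obs, resp, truth = simulate_homogeneous(380, seed=7)
    return {"observations": obs, "data": ChoiceData(obs), "truth": truth}


@pytest.fixture(scope="session")
def heteroskedastic_study():
    obs, resp, truth = simulate_homogeneous(380, seed=8, gamma=SyntheticTruth().gamma)
    return {"observations": obs, "data": ChoiceData(obs), "truth": truth}
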