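import numpy as np
import pandas as pd
import pytest

from wqslearn import GeneratorConfig, simulate_cohort
from wqslearn.config import COMPONENTS
from wqslearn.quantiles import decile_transform


def make_config(**overrides) -> GeneratorConfig:
    d = GeneratorConfig().to_dict()
    d.update(overrides)
    return GeneratorConfig.from_dict(d)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-subject default-calibration cohort (fast fixture for unit tests)."""
    return simulate_cohort(make_config(n_subjects=60, seed=7))


@pytest.fixture(scope="session")
def default_cohort():
    """The full default cohort (n=188, seed 1)."""
    return simulate_cohort(make_config(seed=1))


@pytest.fixture(scope="session")
def small_Q(small_cohort):
    return decile_transform(small_cohort["exposures"][list(COMPONENTS)])


@pytest.fixture(scope="session")
def small_sex(small_cohort):
    return small_cohort["subjects"]["sex"].to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def planted_response(Q, weights, beta, noise_sd, rng, sex=None, beta_girl=None):
    """y = beta * (Q @ w) + noise, optionally sex-specific slopes."""
    idx = np.asarray(Q, dtype=float) @ np.asarray(weights, dtype=float)
    if sex is not None:
        girl = (np.asarray(sex) == "girl") | (np.asarray(sex) == 1)
        b = np.where(girl, beta_girl, beta)
    else:
        b = beta
    return b * idx + rng.normal(0.0, noise_sd, size=len(idx))
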