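import warnings

import numpy as np
import pandas as pd
import pytest

from paradetect import load_default_profiles, simulate_cohort


@pytest.fixture(scope="session")
def profiles():
    return load_default_profiles()


@pytest.fixture(scope="session")
def default_cohort(profiles):
    """One simulated cohort at the study's scale, shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(profiles, seed=20240515)


def nb_draw(rng: np.random.Generator, mu, k, size=None):
    """Independent NB2 sampler used by test oracles."""
    mu = np.asarray(mu, dtype=float)
    if np.isinf(k):
        return rng.poisson(mu, size=size)
    return rng.poisson(rng.gamma(k, mu / k, size=size))


def two_group_design(n_per_group: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "intercept": np.ones(2 * n_per_group),
            "treatment": np.r_[np.zeros(n_per_group), np.ones(n_per_group)],
        }
    )
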