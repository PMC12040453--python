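import numpy as np
import pytest

import radpop as rp


@pytest.fixture(scope="session")
def design():
    return rp.ExperimentDesign(seed=7)


@pytest.fixture(scope="session")
def curves(design):
    """One full synthetic experiment (24 curves, 15% noise, seeded)."""
    return rp.generate_timecourses(design)


@pytest.fixture(scope="session")
def noiseless_curves():
    return rp.generate_timecourses(
        rp.ExperimentDesign(noise_cv=0.0, seed=0)
    )


@pytest.fixture(scope="session")
def hour_grid():
    return np.arange(0.0, 144.001, 1.5)


def random_valid_params(rng, dose=10.0, Ta=18.0):
    """Draw a parameter set uniformly within the fitting bounds."""
    gamma = 0.06
    lambda_s = rng.uniform(0.0, gamma)
    lambda_u = rng.uniform(0.0, 0.2)
    lambda_r = rng.uniform(0.0, 0.2)
    return rp.ModelParams(
        dose=dose,
        Ta=Ta,
        gamma=gamma,
        lambda_s=lambda_s,
        lambda_u=lambda_u,
        lambda_r=lambda_r,
    )
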