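import numpy as np
import pandas as pd
import pytest

from sericata import constants
from sericata.growth import fit_length_models
from sericata.synthetic import CohortDesign, GenerativeTruth, simulate_experiment


@pytest.fixture(scope="session")
def printed_mean_times():
    """Published per-temperature mean egg-to-adult development times (days)."""
    return dict(constants.MEAN_DEV_TIME_DAYS)


def generate_length_adh(rng, n=973, sigma=0.083, b0=2.295, b1=0.327):
    """Draw (length, ADH) pairs from the log-log length law.

    Lengths are log-uniform over the feeding calibration range; Log10(ADH)
    gets Gaussian noise of scale ``sigma``.
    """
    x = 10 ** rng.uniform(0.0, np.log10(16.0), n)
    log_adh = b0 + b1 * np.log10(x) + rng.normal(0.0, sigma, n)
    return x, 10.0**log_adh


@pytest.fixture(scope="session")
def length_adh_sample():
    """One seeded draw from the log-log length law at the published scale."""
    return generate_length_adh(np.random.default_rng(7))


@pytest.fixture(scope="session")
def default_run():
    """One full-design simulation with default noise (seeded)."""
    return simulate_experiment(seed=1)


@pytest.fixture(scope="session")
def noiseless_run():
    """Full-design simulation with no threshold noise (stage timing exact)."""
    return simulate_experiment(truth=GenerativeTruth(threshold_cv=0.0), seed=2)


@pytest.fixture(scope="session")
def small_run():
    """A light simulation for CLI and I/O tests."""
    design = CohortDesign(temperatures_c=(22.0, 26.0, 30.0), replicates=2,
                          eggs_per_bottle=10, bottles=4)
    return simulate_experiment(design, seed=3)
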