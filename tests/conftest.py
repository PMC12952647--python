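import numpy as np
import pandas as pd
import pytest

from eggsig import RejectionModel, TraitSpec, generate_population


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def continuous_spec():
    return TraitSpec(name="a", kind="continuous", population_mean=0.5,
                     overall_sd=0.25, within_clutch_sd=0.05)


@pytest.fixture(scope="session")
def categorical_spec():
    # d^2 + s^2 = 0.2^2 + 0.15^2 = 0.0625 = 0.25^2
    return TraitSpec(name="c", kind="categorical2", population_mean=0.5,
                     overall_sd=0.25, peak_half_distance=0.2,
                     within_peak_sd=0.15, within_clutch_sd=0.05)


@pytest.fixture(scope="session")
def small_population(continuous_spec):
    return generate_population([continuous_spec], n_clutches=10,
                               eggs_per_clutch=2, seed=77)


@pytest.fixture(scope="session")
def known_model():
    return RejectionModel(intercept=-2.0, coefficients={"a": 4.0})


@pytest.fixture(scope="session")
def bimodal_sample(rng):
    """Well-separated bimodal data (peak separation 10 within-peak sd)."""
    return np.sort(np.concatenate([rng.normal(0.0, 0.1, 100),
                                   rng.normal(1.0, 0.1, 100)]))


@pytest.fixture(scope="session")
def unimodal_sample(rng):
    return np.sort(rng.normal(0.0, 1.0, 200))
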