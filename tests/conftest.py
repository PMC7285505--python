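"""Shared fixtures: small synthetic farm datasets and a quickly trained model.

Everything is generated programmatically and seeded; session scope keeps the
one genuinely expensive fixture (a trained network) to a single build.
"""

import numpy as np
import pytest

import dairytherm as dt
from dairytherm import brann


@pytest.fixture(scope="session")
def small_weather():
    """Two years of daily-max weather (default climate), seed 101."""
    return dt.generate_weather(730, dt.WeatherSimParams(seed=101))


@pytest.fixture(scope="session")
def small_derived(small_weather):
    return dt.derive_weather_frame(small_weather)


@pytest.fixture(scope="session")
def small_herd():
    return dt.generate_herd(8, bv_range=(93.0, 112.0), seed=102)


@pytest.fixture(scope="session")
def small_cow_days(small_derived, small_herd):
    return dt.generate_cow_days(small_derived, small_herd, dt.ResponseParams(seed=103))


@pytest.fixture(scope="session")
def small_features(small_derived, small_cow_days):
    return dt.assemble_features(small_derived, small_cow_days)


@pytest.fixture(scope="session")
def trained_model(small_features):
    """A briefly trained network on the small farm (enough for plumbing
    tests; accuracy-sensitive tests train their own)."""
    model, split = brann.fit_model(
        small_features, brann.TrainConfig(max_epochs=25, seed=104)
    )
    return model, split


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
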