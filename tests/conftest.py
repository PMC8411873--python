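"""Shared fixtures: small, fast synthetic configurations."""

from dataclasses import replace

import numpy as np
import pytest

from firehealth.config import FirePlume, SyntheticConfig, demo_config
from firehealth.synthetic import (
    generate_imr_grid,
    generate_population,
    generate_scenario_pair,
)


@pytest.fixture(scope="session")
def small_config():
    """Coarse 20x20 grid, one plume centred exactly on a cell centre."""
    return SyntheticConfig(
        resolution=0.5,
        plumes=(FirePlume(lat=15.25, lon=100.25, amplitude=30.0, decay_km=200.0),),
        concentration_noise_sd=0.0,
        o3_daily_noise_sd=0.0,
        station_noise_sd=0.0,
        station_bias=1.0,
        imr_noise_sd=0.0,
        n_days=60,
        seed=7,
    )


@pytest.fixture(scope="session")
def noisy_config(small_config):
    return replace(
        small_config,
        concentration_noise_sd=0.1,
        o3_daily_noise_sd=0.05,
        imr_noise_sd=10.0,
        station_noise_sd=3.0,
        station_bias=1.25,
    )


@pytest.fixture(scope="session")
def pair(small_config):
    return generate_scenario_pair(small_config)


@pytest.fixture(scope="session")
def noisy_pair(noisy_config):
    return generate_scenario_pair(noisy_config)


@pytest.fixture(scope="session")
def population(small_config):
    return generate_population(small_config)


@pytest.fixture(scope="session")
def imr(small_config, pair):
    return generate_imr_grid(small_config, pair.fire_pm25_annual())


@pytest.fixture(scope="session")
def demo_cfg():
    return demo_config(seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
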