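"""Shared fixtures: small deterministic surveys and sighting factories."""

from __future__ import annotations

import numpy as np
import pytest

from tandemair.core import Category, Platform, Sighting
from tandemair.simulate import SimulationConfig, SpeciesConfig, simulate_survey


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sighting(sighting_id="s1", platform=Platform.SCANS, time=0.0,
                  x=0.0, y=0.0, side="L", angle=60.0,
                  category=Category.CETACEAN, species="harbour_porpoise",
                  group_size=1):
    return Sighting(sighting_id, platform, time, x, y, side, angle,
                    category, species, group_size)


@pytest.fixture
def sighting_factory():
    return make_sighting


def noise_free_config(seed=11, density=0.08):
    """Simulator settings with all recording error switched off."""
    return SimulationConfig(
        seed=seed,
        region_width_km=60.0,
        region_height_km=40.0,
        n_transects=6,
        species=(SpeciesConfig("hp", density=density, sigma_scans=250.0,
                               sigma_mega=250.0),),
        baseline_logit_p={Platform.SCANS: 1.5, Platform.MEGAFAUNA: 1.5},
        gps_jitter_sd=0.0,
        recording_delay_max=0.0,
        angle_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def noise_free_survey():
    return simulate_survey(noise_free_config())


@pytest.fixture(scope="session")
def default_survey():
    return simulate_survey(SimulationConfig(seed=7))


def cetaceans(survey, platform):
    return [s for s in survey.sightings[platform] if s.category == Category.CETACEAN]
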