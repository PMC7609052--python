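"""Shared fixtures: small synthetic worlds reused across test modules."""

import numpy as np
import pytest

from plumewalk.signal_encounters import BackgroundModel
from plumewalk.stopwalk_models import fitted_stop_spec, fitted_walk_spec
from plumewalk.synthetic_world import (EncounterTrainConfig, PlumeConfig,
                                       generate_encounter_train,
                                       generate_plume_field,
                                       simulate_ground_truth_behavior)
from plumewalk.turn_model import TurnModelParams

DT = 1.0 / 90.0


@pytest.fixture(scope="session")
def plume_config():
    return PlumeConfig(seed=1)


@pytest.fixture(scope="session")
def plume_field(plume_config):
    return generate_plume_field(plume_config, 60.0)


@pytest.fixture(scope="session")
def plume_movie(plume_field):
    # 1 mm rendering keeps the 60 s movie small while preserving the
    # packet structure (packets are >= 2.5 mm)
    return plume_field.render_movie(pixel_size=1.0)


@pytest.fixture(scope="session")
def background(plume_config):
    return BackgroundModel(mean=plume_config.background_mean,
                           sd=plume_config.background_noise_sd)


@pytest.fixture(scope="session")
def behavior_ensemble():
    """60 labeled trajectories on heterogeneous-rate Poisson trains."""
    rates = np.linspace(0.2, 6.0, 60)
    trains = [generate_encounter_train(EncounterTrainConfig(
        onset_rate=float(r), duration_sampler=("constant", {"value": 0.1}),
        total_time=60.0, seed=300 + i)) for i, r in enumerate(rates)]
    return simulate_ground_truth_behavior(
        TurnModelParams(), fitted_stop_spec(), fitted_walk_spec(),
        trains, 60, seed=21)
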