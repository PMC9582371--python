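"""Shared fixtures: scaled-down study conditions generated at test time."""

import numpy as np
import pytest

from selfcontrol_fmri import datasets, simulate
from selfcontrol_fmri.config import SimConfig

# Desk-scale problem sizes: 16 stimuli fit comfortably into a 130-volume run
# with the task's 4-15 s ITIs, and a 12^3 grid keeps every labeled region
# multi-voxel while first-level fits stay sub-second.
TEST_KW = dict(n_stimuli=16, n_volumes_per_run=130, grid_shape=(12, 12, 12))


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_subjects=12, frac_sc=0.4, seed=7, **TEST_KW)


@pytest.fixture(scope="session")
def noisefree_config() -> SimConfig:
    return SimConfig(
        n_subjects=4, frac_sc=0.5, seed=7, noise_sd=0.0, drift_amplitude=0.0,
        neural_fluct_sd=0.0, rating_noise_sd=0.0, decision_noise=0.0,
        missing_prob=0.0, **TEST_KW)


@pytest.fixture(scope="session")
def labels(small_config):
    return simulate.make_region_labels(small_config.grid_shape)


@pytest.fixture(scope="session")
def stimuli(small_config):
    rng = np.random.default_rng(small_config.seed)
    return simulate.simulate_stimuli(small_config, rng)


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, small_config):
    path = tmp_path_factory.mktemp("data") / "ds"
    simulate.generate_dataset(small_config, path)
    return path


@pytest.fixture(scope="session")
def dataset(dataset_dir):
    return datasets.read_dataset(dataset_dir)
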