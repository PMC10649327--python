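"""Shared fixtures: a small phantom cohort at the fast profile and the
expensive trained models, computed once per session."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from hippoloc import classify, dqn, env, phantom, preprocess

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def fast_config():
    return phantom.FAST_PHANTOM_CONFIG


@pytest.fixture(scope="session")
def fast_dataset(fast_config):
    # 40 training / 10 held-out subjects, balanced classes
    return phantom.generate_dataset(fast_config, n_per_class=25, seed=1)


@pytest.fixture(scope="session")
def train_volumes(fast_dataset):
    return fast_dataset.volumes("train")


@pytest.fixture(scope="session")
def test_volumes(fast_dataset):
    return fast_dataset.volumes("test")


@pytest.fixture(scope="session")
def train_slices(train_volumes):
    return preprocess.make_slice_dataset(train_volumes, target_hw=(128, 128))


@pytest.fixture(scope="session")
def train_stats(train_volumes):
    return preprocess.NormalizationStats.from_arrays(
        [v.image[preprocess.select_optimal_slice(v.mask)] for v in train_volumes]
    )


@pytest.fixture(scope="session")
def test_slices(test_volumes, train_stats):
    return preprocess.make_slice_dataset(test_volumes, target_hw=(128, 128),
                                         stats=train_stats)


@pytest.fixture(scope="session")
def noop_env_config():
    return dataclasses.replace(
        env.FAST_ENV_CONFIG, termination_strategy=env.TerminationStrategy.NOOP
    )


@pytest.fixture(scope="session")
def trained_agent(train_slices, noop_env_config):
    """The scaled-down 2D DQN training run (200 episodes); ~2.5 min."""
    return dqn.train_dqn(train_slices, noop_env_config, dqn.FAST_DQN_CONFIG)


@pytest.fixture(scope="session")
def gt_crop_data(train_slices, test_slices):
    size = classify.FAST_CLASSIFIER_CONFIG.crop_size
    Xtr = np.stack([classify.crop_and_resize(s.image, s.gt_box, size) for s in train_slices])
    Xte = np.stack([classify.crop_and_resize(s.image, s.gt_box, size) for s in test_slices])
    return (
        Xtr,
        np.array([s.label for s in train_slices]),
        Xte,
        np.array([s.label for s in test_slices]),
    )
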