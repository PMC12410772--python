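"""Shared fixtures: small synthetic cohorts, generated at test time."""

from __future__ import annotations

import pytest

import runkinetics as rk
from runkinetics.experiments import prepare_dataset
from runkinetics.synthetic import SettingShift, SimConfig, generate_runner, generate_session


def noise_free_profile(seed: int = 5, **overrides) -> rk.RunnerProfile:
    """A runner profile with measurement noise switched off."""
    p = generate_runner(seed)
    p.noise_sd = {"acc": 0.0, "gyro": 0.0, "angle": 0.0}
    for k, v in overrides.items():
        setattr(p, k, v)
    return p


@pytest.fixture(scope="session")
def clean_session():
    """One noise-free treadmill session with its ground truth."""
    profile = noise_free_profile(5)
    cfg = SimConfig(seed=40, duration=40.0)
    return generate_session(profile, SettingShift.treadmill(), cfg)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Three runners, treadmill + overground (+1 outdoor), 30 s sessions."""
    return rk.make_dataset(SimConfig(seed=11, duration=30.0, n_runners=3,
                                     n_outdoor=1, speed_segment_s=7.0))


@pytest.fixture(scope="session")
def tiny_prepared(tiny_dataset):
    return prepare_dataset(tiny_dataset)
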