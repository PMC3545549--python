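"""Shared fixtures: simulated trials and pipeline runs reused across tests."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from swimvel.detrend import TrialInfo
from swimvel.pipeline import RunConfig, estimate_velocity
from swimvel.simulator import scenario, simulate_swim


@pytest.fixture(scope="session")
def elite3_noisy():
    """elite_t3 preset with its default sensor imperfections, seed 0."""
    cfg = scenario("elite_t3")
    truth, recording, reference = simulate_swim(cfg)
    return cfg, truth, recording, reference


@pytest.fixture(scope="session")
def elite3_clean():
    """elite_t3 with every stochastic disturbance and bias removed."""
    cfg = dataclasses.replace(
        scenario("elite_t3"),
        gyro_noise_sd=0.0, accel_noise_sd=0.0, pitch_yaw_jitter=0.0,
        gyro_bias=(0.0, 0.0, 0.0), accel_bias=(0.0, 0.0, 0.0),
    )
    truth, recording, reference = simulate_swim(cfg)
    return cfg, truth, recording, reference


@pytest.fixture(scope="session")
def elite3_noisy_run(elite3_noisy):
    """Full pipeline result on the noisy elite_t3 trial."""
    cfg, truth, recording, reference = elite3_noisy
    trial = TrialInfo(pool_length=truth.distance, duration=recording.duration)
    result = estimate_velocity(recording, trial, RunConfig())
    return truth, recording, reference, trial, result


@pytest.fixture(scope="session")
def elite3_clean_run(elite3_clean):
    """Full pipeline result on the disturbance-free elite_t3 trial."""
    cfg, truth, recording, reference = elite3_clean
    trial = TrialInfo(pool_length=truth.distance, duration=recording.duration)
    result = estimate_velocity(recording, trial, RunConfig())
    return truth, recording, reference, trial, result


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
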