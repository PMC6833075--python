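"""Shared fixtures: tiny synthetic cohorts sized for fast unit tests."""

import numpy as np
import pytest

from painfusion.synthetic import (
    GeneratorConfig,
    make_schedule,
    sample_profile,
    simulate_cohort_arrays,
    simulate_subject,
)


@pytest.fixture(scope="session")
def tiny_config():
    """Two subjects, two reps per level, generated directly at 256 Hz."""
    return GeneratorConfig(n_subjects=2, reps_per_level=2, fs_hz=256.0, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort_arrays(tiny_config)


@pytest.fixture(scope="session")
def tiny_recording(tiny_config):
    schedule = make_schedule(tiny_config, 0)
    profile = sample_profile(tiny_config, 0, "S000")
    return simulate_subject(profile, schedule, tiny_config, seed=0)


@pytest.fixture(scope="session")
def native_rate_config():
    """One subject at the native 512 Hz generation rate."""
    return GeneratorConfig(n_subjects=1, reps_per_level=2, fs_hz=512.0, seed=3)


@pytest.fixture(scope="session")
def native_rate_recording(native_rate_config):
    schedule = make_schedule(native_rate_config, 0)
    profile = sample_profile(native_rate_config, 0, "S000")
    return simulate_subject(profile, schedule, native_rate_config, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
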