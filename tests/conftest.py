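import numpy as np
import pytest
from hypothesis import settings

from fingercoord import synth

settings.register_profile(
    "ci", max_examples=50, derandomize=True, deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def subject() -> synth.SubjectProfile:
    return synth.SubjectProfile(
        subject_id="data01",
        middle_length_mm=84.8,
        ring_length_mm=80.3,
        training_years=10.0,
    )


@pytest.fixture
def noiseless_config() -> synth.GeneratorConfig:
    return synth.GeneratorConfig(
        n_subjects=1,
        sets_per_subject=2,
        keystrokes_per_set=5,
        angle_noise_sd_deg=0.0,
        position_noise_sd_mm=0.0,
    )


@pytest.fixture
def noiseless_set(subject, noiseless_config) -> synth.HandTrajectory:
    return synth.generate_session(subject, noiseless_config)[0]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
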