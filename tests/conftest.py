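import numpy as np
import pytest

from kneeload.muscles import MomentArmModel
from kneeload.subjects import SubjectProfile
from kneeload.synthetic import (
    GaitTrialSpec,
    StsTrialSpec,
    generate_gait_trial,
    generate_sts_trace,
)

ZERO_NOISE = {"grf": 0.0, "moments": 0.0, "angles": 0.0, "pelvis_vz": 0.0}


@pytest.fixture(scope="session")
def male_subject():
    return SubjectProfile(gender="male", height_m=1.751, mass_kg=71.8, subject_id="m-test")


@pytest.fixture(scope="session")
def female_subject():
    return SubjectProfile(gender="female", height_m=1.628, mass_kg=59.9, subject_id="f-test")


@pytest.fixture(scope="session")
def male_model(male_subject):
    return MomentArmModel.for_subject(male_subject)


@pytest.fixture(scope="session")
def clean_walk(male_subject):
    """Noise-free walking trial with its planted ground truth."""
    spec = GaitTrialSpec(
        movement_class="walk", subject=male_subject, noise_sd=dict(ZERO_NOISE), seed=11
    )
    return generate_gait_trial(spec), spec


@pytest.fixture(scope="session")
def clean_sts():
    """Noise-free sit-stand-sit trace with planted ground truth."""
    spec = StsTrialSpec(seed=11)
    return generate_sts_trace(spec), spec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
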