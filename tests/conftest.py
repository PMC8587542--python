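"""Shared fixtures: one subject, scaled model, and synthetic trials.

Trials are session-scoped (deterministic, seeded) so the expensive
generators run once per test session.
"""

import numpy as np
import pytest

from wbid import SubjectRecord, build_body_model
from wbid.synthetic import generate_gait, generate_lift, generate_stand


@pytest.fixture(scope="session")
def subject():
    # population mean of the study conditions: 177.3 cm, 78.9 kg
    return SubjectRecord(height=1.773, mass=78.9, sex="male")


@pytest.fixture(scope="session")
def model(subject):
    return build_body_model(subject)


@pytest.fixture(scope="session")
def stand_trial(subject):
    return generate_stand(subject, duration=4.0, seed=0)


@pytest.fixture(scope="session")
def sway_trial(subject):
    return generate_stand(subject, duration=4.0, sway_amplitude=0.02, seed=0)


@pytest.fixture(scope="session")
def offset_stand_trial(subject):
    return generate_stand(subject, duration=1.0, lateral_offset=0.05, seed=0)


@pytest.fixture(scope="session")
def gait_trial(subject):
    return generate_gait(subject, speed=1.1, n_cycles=2, seed=1)


@pytest.fixture(scope="session")
def lift_trial(subject):
    return generate_lift(subject, box_mass=17.0, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
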