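import numpy as np
import pytest

from uvcoverage.facial_regions import regions_from_landmarks
from uvcoverage.synthetic_data import (
    ParticipantSpec,
    generate_landmark_template,
    generate_participant,
)


@pytest.fixture(scope="session")
def template():
    """Jitter-free 68-point template on a 128x128 frame."""
    return generate_landmark_template((128, 128), jitter_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def regions(template):
    return regions_from_landmarks(template)


@pytest.fixture(scope="session")
def bundle():
    """One synthetic participant with 15% of the face left uncovered."""
    spec = ParticipantSpec("P001", true_missed_fraction={"face": 0.15})
    return generate_participant(spec, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
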