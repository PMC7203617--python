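import numpy as np
import pandas as pd
import pytest

from gazephen import default_geometry
from gazephen.synth import make_schedule
from gazephen.synth.cohort import Participant, uniform_confusion_profile


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def small_schedule():
    """Two short trials at a low frame rate, with one dot event each."""
    return make_schedule(trial_sizes=(8, 8), frame_rate=5, seed=0)


@pytest.fixture(scope="session")
def full_schedule():
    """Study-sized trials (41, 42, 41) at a reduced frame rate."""
    return make_schedule(trial_sizes=(41, 42, 41), frame_rate=5, seed=0)


def make_participant(
    pid="p01",
    group="ASD",
    distraction=0.1,
    offtask=0.05,
    accuracy=0.7,
    age=10,
    gender="male",
):
    return Participant(
        participant_id=pid,
        group=group,
        age=age,
        gender=gender,
        latent_distraction=distraction,
        latent_offtask=offtask,
        confusion_profile=uniform_confusion_profile(accuracy),
    )


@pytest.fixture()
def participant():
    return make_participant()


@pytest.fixture()
def render_stream():
    """Normalized pupil positions for renderer-based detector tests."""
    rng = np.random.default_rng(7)

    def _make(n, seed=7):
        r = np.random.default_rng(seed)
        return pd.DataFrame(
            {"x": r.random(n), "y": r.random(n), "missing": False}
        )

    return _make
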