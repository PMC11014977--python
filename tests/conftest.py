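import numpy as np
import pytest

from mixedintentions.models import get_model
from mixedintentions.task import build_schedule, play_session


@pytest.fixture(scope="session")
def schedule():
    """The study-shaped 163-trial schedule."""
    return build_schedule(163, 5, 13, 10)


@pytest.fixture(scope="session")
def wsls_session(schedule):
    """One deterministic session of a lapsing WSLS agent vs the live AA."""
    return play_session(
        get_model("WSLS"), {"epsilon": 0.1}, schedule, seed=11, subject_id="w1"
    )


@pytest.fixture(scope="session")
def mixed_params():
    """A representative mixed-intentions parameter set (natural scale)."""
    return {
        "eta": 0.3,
        "kappa": 0.6,
        "beta": 3.5,
        "slope": 12.0,
        "delta_bias": 0.1,
    }


@pytest.fixture(scope="session")
def mixed_session(schedule, mixed_params):
    return play_session(
        get_model("INF_MIXED"), mixed_params, schedule, seed=21, subject_id="m1"
    )
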