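import numpy as np
import pytest

import spikelick as sl
from spikelick.types import LickTrain, Trial


@pytest.fixture(scope="session")
def lean_session():
    """One small lean session shared by read-only tests."""
    session, specs = sl.generate_session("lean", 8, 6, rng=7)
    return session, specs


@pytest.fixture()
def empty_licks():
    return LickTrain(np.array([]), np.array([], dtype=object))


def make_trials(n_trials: int, spacing: float = 8.0, start: float = 5.0,
                stimulus: str = "X", ili: float = 0.16) -> list[Trial]:
    """Evenly spaced synthetic trials with 5 regularly spaced licks."""
    return [
        Trial(stimulus, start + spacing * k + ili * np.arange(5))
        for k in range(n_trials)
    ]


@pytest.fixture()
def trials20():
    return make_trials(20)
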