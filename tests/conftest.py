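import numpy as np
import pandas as pd
import pytest

from wildna.event_data import TransitionKey, build_counting_data
from wildna.nelson_aalen import fit_nelson_aalen
from wildna.simulate import _counting_from_exits


@pytest.fixture
def toy_frame():
    """Three subjects: events 0→2 at t=1 and t=2, one censoring at 2.5."""
    return pd.DataFrame(
        {
            "id": ["a", "b", "c"],
            "entry": [0.0, 0.0, 0.0],
            "exit": [1.0, 2.0, 2.5],
            "from": ["0", "0", "0"],
            "to": ["2", "2", "cens"],
        }
    )


@pytest.fixture
def toy_cd(toy_frame):
    """jump times (1, 2), ΔN = (1, 1), Y = (3, 2), n = 3, τ = 3."""
    return build_counting_data(toy_frame, TransitionKey("0", "2"), tau=3.0)


@pytest.fixture
def toy_fit(toy_cd):
    return fit_nelson_aalen(toy_cd)


@pytest.fixture
def survival_cd():
    """n = 200 exponential(1) survival times, no censoring, τ = 1."""
    rng = np.random.default_rng(20240)
    n = 200
    t = rng.exponential(1.0, n)
    return _counting_from_exits(
        t, np.ones(n, dtype=int), 1, 1.0, n, TransitionKey("0", "1")
    )
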