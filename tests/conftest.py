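import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_fixation_table(aois, participant="P01", session="S1", onset0=0.0,
                        duration=500.0, confidence=1.0):
    """Minimal well-formed fixation table around a symbol sequence."""
    n = len(aois)
    onsets = onset0 + np.arange(n) * 0.55
    return pd.DataFrame(
        {
            "participant": participant,
            "session": session,
            "onset": onsets,
            "duration_ms": duration,
            "aoi": np.asarray(aois, dtype=np.int64),
            "confidence": confidence,
        }
    )


@pytest.fixture()
def toy_labeled(rng):
    """A labeled single-participant table with one valid trial."""
    from scanpath_ais.io import assign_periods

    table = make_fixation_table(rng.integers(1, 9, 40))
    events = pd.DataFrame(
        {
            "trial_id": [1],
            "onset": [table.onset[12] - 0.01],
            "lane_change": [table.onset[20] - 0.01],
            "end": [table.onset[30] + 0.1],
            "difficulty": ["easy"],
            "valid": [True],
        }
    )
    return assign_periods(table, events)
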