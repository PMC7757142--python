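import numpy as np
import pandas as pd
import pytest

from fusbbb import EmissionModel, GroupClosureFixture, SonicationConfig


@pytest.fixture
def config():
    return SonicationConfig()


@pytest.fixture
def emission_model():
    return EmissionModel(onset_pressure_uh=0.36, onset_pressure_sh=0.36, seed=7)


def random_closure_table(rng, group, n, p=(0.3, 0.2, 0.2, 0.3)):
    """Random discrete closure table: events at 6/12/20 h or censored at 20 h."""
    cats = rng.choice(4, size=n, p=np.asarray(p) / np.sum(p))
    times = np.array([6.0, 12.0, 20.0, 20.0])[cats]
    events = np.where(cats == 3, "censored", "closed")
    return pd.DataFrame(
        {
            "mouse": [f"{group}-m{i // 4}" for i in range(n)],
            "focus": [i % 4 for i in range(n)],
            "group": group,
            "event_time_h": times,
            "event": events,
        }
    )
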