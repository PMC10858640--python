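import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import hfscore as h

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort with repeat events and transmission gaps."""
    cfg = h.CohortConfig(
        n_event_patients=30, n_control_patients=60, total_events=43, seed=17
    )
    patients, events = h.make_cohort(cfg)
    return cfg, patients, events


@pytest.fixture(scope="session")
def small_weekly(small_cohort):
    """Weekly observations from the small cohort (default trajectory)."""
    cfg, patients, events = small_cohort
    scores = h.simulate_component_scores(
        patients, events, seed=18, transmission_probability=0.9
    )
    anchors = h.select_anchors(patients, events, scores)
    weekly = h.build_weekly_observations(anchors, scores)
    return patients, events, anchors, weekly


def constant_telemetry_window(n_days=84, *, hr24=70.0, night_hr=60.0, hrv=100.0,
                              ahre=0.0, pvc=2.0, activity=10.0, impedance=70.0):
    """One fully transmitted window with constant channels."""
    return pd.DataFrame(
        {
            "day": np.arange(n_days),
            "hr24": hr24,
            "night_hr": night_hr,
            "hrv": hrv,
            "ahre_pct": ahre,
            "pvc_per_h": pvc,
            "activity": activity,
            "impedance": impedance,
            "transmitted": True,
        }
    )
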