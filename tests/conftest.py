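import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import prevently as pv

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort() -> pv.SyntheticCohort:
    """10 participants x 150 days, clean observation layer."""
    cfg = pv.SimConfig(n_participants=10, followup_days=150, seed=2024)
    return pv.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_panel(small_cohort) -> pd.DataFrame:
    metas = [
        pv.ParticipantMeta(r.participant_id, r.enrolment_date, r.end_date)
        for r in small_cohort.participants.itertuples()
    ]
    return pv.build_cohort_panel(
        small_cohort.cap_events, small_cohort.weekly_surveys, metas
    )


def random_panel(rng: np.random.Generator, n_days: int) -> pd.DataFrame:
    """A one-participant panel with random dosing/CAS and observation gaps."""
    from datetime import date, timedelta

    start = date(2020, 2, 1) + timedelta(days=int(rng.integers(0, 60)))
    dates = [start + timedelta(days=i) for i in range(n_days)]
    t = np.array([(d - date(2020, 3, 16)).days for d in dates])
    dose = rng.integers(0, 2, n_days)
    observed_cas = rng.random(n_days) < 0.8
    cas = np.where(observed_cas, rng.random(n_days) < 0.3, np.nan)
    panel = pd.DataFrame(
        {
            "participant_id": "PX",
            "date": dates,
            "t": t,
            "pandemic": (t >= 0).astype(int),
            "dose_day": dose,
            "opening_count": dose,
            "cas_day": pd.array(
                [np.nan if not o else float(c) for o, c in zip(observed_cas, cas)],
                dtype="Float64",
            ),
            "episode_count": pd.array(
                [
                    np.nan if not o else float(rng.integers(1, 4)) * c
                    for o, c in zip(observed_cas, cas)
                ],
                dtype="Float64",
            ),
            "partner_count": pd.array(
                [np.nan if not o else float(rng.integers(1, 3)) * c for o, c in zip(observed_cas, cas)],
                dtype="Float64",
            ),
            "observed_dose": 1,
            "observed_cas": observed_cas.astype(int),
            "excluded_sensitivity": 0,
        }
    )
    return panel
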