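"""Prevention-effective adherence: episode coverage and descriptive statistics.

A condomless-anal-sex (CAS) episode on day d is *covered* by daily PrEP when
the cap recorded a dose on each of the ``days_before`` days immediately
preceding d and each of the ``days_after`` days immediately following it
(defaults 3 before / 2 after; optionally also on d itself).  If any required
day falls outside the participant's observed window the episode is
*unassessable* and excluded from coverage denominators.  All episodes
reported for one day share that day's status.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import ParticipantMeta

__all__ = [
    "CoverageRule",
    "classify_day",
    "classify_episodes",
    "flag_inconsistent_periods",
    "coverage_summary",
    "descriptive_stats",
    "SELFREPORT_PERCENT",
]

logger = logging.getLogger(__name__)

COVERED, UNCOVERED, UNASSESSABLE = "covered", "uncovered", "unassessable"

# Percent of days each self-reported use level is taken to represent when
# screening follow-up intervals for inconsistent MEMS use.
SELFREPORT_PERCENT = {
    "daily": 100.0,
    "most days": 75.0,
    "about half": 50.0,
    "occasionally": 25.0,
    "rarely or never": 5.0,
}

EPISODE_COLUMNS = [
    "participant_id",
    "date",
    "t",
    "pandemic",
    "n_episodes_on_day",
    "status",
    "excluded_sensitivity",
]


@dataclass(frozen=True)
class CoverageRule:
    days_before: int = 3
    days_after: int = 2
    require_event_day_dose: bool = False

    def __post_init__(self) -> None:
        if self.days_before < 0 or self.days_after < 0:
            raise ValueError("coverage window lengths must be >= 0")

    def required_offsets(self) -> list[int]:
        offs = list(range(-self.days_before, 0)) + list(range(1, self.days_after + 1))
        if self.require_event_day_dose:
            offs.insert(self.days_before, 0)
        return offs


def classify_day(panel: pd.DataFrame, cas_date, rule: CoverageRule = CoverageRule()) -> str:
    """Coverage status of the CAS day ``cas_date`` in a one-participant panel."""
    sub = panel.set_index("date") if panel.index.name != "date" else panel
    if cas_date not in sub.index:
        raise ValueError(f"{cas_date} is not in the panel")
    row = sub.loc[cas_date]
    if pd.isna(row["cas_day"]) or int(row["cas_day"]) != 1:
        raise ValueError(f"{cas_date} is not a CAS day")
    t0 = int(row["t"])
    t_index = sub["t"].to_numpy(dtype=int)
    observed = sub["observed_dose"].to_numpy(dtype=bool)
    dosed = sub["dose_day"].to_numpy(dtype=bool) & observed
    lookup = {int(t): i for i, t in enumerate(t_index)}
    required = [t0 + off for off in rule.required_offsets()]
    if any(t not in lookup or not observed[lookup[t]] for t in required):
        return UNASSESSABLE
    if all(dosed[lookup[t]] for t in required):
        return COVERED
    return UNCOVERED


def classify_episodes(panel: pd.DataFrame, rule: CoverageRule = CoverageRule()) -> pd.DataFrame:
    """Classify every CAS day of a cohort panel; one row per CAS *day*.

    ``n_episodes_on_day`` carries the (capped) episode count so that
    summaries can weight by episodes; every episode on a day inherits the
    day's status.  Participants on an event-based regimen must be excluded
    upstream (see :func:`coverage_summary`).
    """
    rows = []
    for pid, sub in panel.groupby("participant_id", sort=True):
        sub = sub.sort_values("date").reset_index(drop=True)
        t = sub["t"].to_numpy(dtype=int)
        offset = int(t[0])
        observed = sub["observed_dose"].to_numpy(dtype=bool)
        dosed = sub["dose_day"].to_numpy(dtype=bool) & observed
        n = len(sub)
        cas_idx = np.flatnonzero(sub["cas_day"].fillna(0).to_numpy(dtype=float) == 1)
        offs = rule.required_offsets()
        for i in cas_idx:
            req = [i + o for o in offs]
            if any(j < 0 or j >= n or not observed[j] for j in req):
                status = UNASSESSABLE
            elif all(dosed[j] for j in req):
                status = COVERED
            else:
                status = UNCOVERED
            epi = sub.at[i, "episode_count"]
            rows.append(
                {
                    "participant_id": pid,
                    "date": sub.at[i, "date"],
                    "t": int(t[i]),
                    "pandemic": int(sub.at[i, "pandemic"]),
                    "n_episodes_on_day": max(1, 0 if pd.isna(epi) else int(epi)),
                    "status": status,
                    "excluded_sensitivity": int(sub.at[i, "excluded_sensitivity"]),
                }
            )
    return pd.DataFrame(rows, columns=EPISODE_COLUMNS)


def flag_inconsistent_periods(
    panel: pd.DataFrame,
    meta: ParticipantMeta,
    threshold: float = 40.0,
    level_percent: dict[str, float] = SELFREPORT_PERCENT,
) -> pd.DataFrame:
    """Set ``excluded_sensitivity`` on follow-up intervals with suspect MEMS use.

    An interval (enrolment to follow-up 1, follow-up 1 to 2, ...) is flagged
    when the absolute gap between the percent of days implied by the
    self-reported use level and the MEMS-derived percent of dose-days exceeds
    ``threshold`` percentage points.  With no self-reports the panel is
    returned unflagged with a warning.
    """
    panel = panel.copy()
    reports = sorted(meta.followup_selfreports)
    if not reports:
        warnings.warn(
            f"{meta.participant_id}: no follow-up self-reports; no intervals flagged",
            stacklevel=2,
        )
        return panel
    mine = panel["participant_id"] == meta.participant_id
    prev = meta.enrolment_date
    for k, (fu_date, level) in enumerate(reports):
        if level not in level_percent:
            raise ValueError(f"unknown self-report level {level!r}")
        if k == 0:  # first interval includes the enrolment day itself
            in_interval = mine & (panel["date"] >= prev) & (panel["date"] <= fu_date)
        else:
            in_interval = mine & (panel["date"] > prev) & (panel["date"] <= fu_date)
        seg = panel[in_interval & (panel["observed_dose"] == 1)]
        if not len(seg):
            prev = fu_date
            continue
        mems_pct = 100.0 * seg["dose_day"].mean()
        if abs(level_percent[level] - mems_pct) > threshold:
            panel.loc[in_interval, "excluded_sensitivity"] = 1
        prev = fu_date
    return panel


def coverage_summary(episodes: pd.DataFrame, sensitivity: bool = False) -> pd.DataFrame:
    """Per-period coverage summary over assessable episodes.

    Episodes (not days) are the denominator: a day with k reported episodes
    contributes k, all with the day's status.  ``sensitivity=True`` restricts
    to intervals not flagged as inconsistent MEMS use.
    ``participants_all_covered`` counts participants whose every assessed
    episode in the period was covered, among those with >=1 assessed episode.
    """
    df = episodes[episodes["status"] != UNASSESSABLE].copy()
    if sensitivity:
        df = df[df["excluded_sensitivity"] == 0]
    rows = []
    for period, flag in (("pre", 0), ("intra", 1)):
        sub = df[df["pandemic"] == flag]
        assessed = int(sub["n_episodes_on_day"].sum())
        covered = int(sub.loc[sub["status"] == COVERED, "n_episodes_on_day"].sum())
        per_part = sub.groupby("participant_id")["status"].agg(
            lambda s: (s == COVERED).all()
        )
        rows.append(
            {
                "period": period,
                "episodes_assessed": assessed,
                "episodes_covered": covered,
                "percent_covered": (100.0 * covered / assessed) if assessed else np.nan,
                "participants_with_cas": int(per_part.size),
                "participants_all_covered": int(per_part.sum()),
                "percent_participants_all_covered": (
                    100.0 * per_part.sum() / per_part.size if per_part.size else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def descriptive_stats(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-period descriptives with observed-day denominators.

    Percent of observed days with a dose (observed_dose denominator), percent
    of observed days with CAS, and mean daily episode / partner counts over
    CAS-observed days.  Means use the capped ordinals (3 = "3 or more",
    2 = "2 or more") and are therefore lower bounds.
    """
    rows = []
    for period, flag in (("pre", 0), ("intra", 1)):
        sub = panel[panel["pandemic"] == flag]
        dose_obs = sub[sub["observed_dose"] == 1]
        cas_obs = sub[sub["observed_cas"] == 1]
        n_dose_days = int(dose_obs["dose_day"].sum())
        n_cas_days = int(cas_obs["cas_day"].sum()) if len(cas_obs) else 0
        rows.append(
            {
                "period": period,
                "observed_days_dose": len(dose_obs),
                "dose_days": n_dose_days,
                "percent_days_dosed": (
                    100.0 * n_dose_days / len(dose_obs) if len(dose_obs) else np.nan
                ),
                "observed_days_cas": len(cas_obs),
                "cas_days": n_cas_days,
                "percent_days_cas": (
                    100.0 * n_cas_days / len(cas_obs) if len(cas_obs) else np.nan
                ),
                "mean_daily_episodes": (
                    float(cas_obs["episode_count"].mean()) if len(cas_obs) else np.nan
                ),
                "mean_daily_partners": (
                    float(cas_obs["partner_count"].mean()) if len(cas_obs) else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
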