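"""Assemble per-participant daily panels from cap events, surveys and metadata.

The panel is the contract consumed by every downstream stage: one row per
participant per calendar day of their observation window, on the
changepoint-centred time axis (t = 0 on the changepoint date, by default
2020-03-16).  Dosing is observed on every in-window day (the cap records
continuously); CAS fields are observed only on surveyed days and are left
missing - never imputed as zero - elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CHANGEPOINT_DEFAULT

__all__ = [
    "ParticipantMeta",
    "WindowError",
    "OverlapError",
    "events_to_daily_use",
    "surveys_to_daily_cas",
    "build_panel",
    "build_cohort_panel",
    "read_meta",
    "write_panel",
    "read_panel",
]

PANEL_COLUMNS = [
    "participant_id",
    "date",
    "t",
    "pandemic",
    "dose_day",
    "opening_count",
    "cas_day",
    "episode_count",
    "partner_count",
    "observed_dose",
    "observed_cas",
    "excluded_sensitivity",
]


class WindowError(ValueError):
    """An event fell outside its participant's observation window."""


class OverlapError(ValueError):
    """Two surveys cover the same day for one participant."""


@dataclass
class ParticipantMeta:
    participant_id: str
    enrolment_date: date
    end_date: date
    regimen: str = "daily"
    followup_selfreports: list = field(default_factory=list)  # (date, level) pairs

    def __post_init__(self) -> None:
        if isinstance(self.enrolment_date, str):
            self.enrolment_date = date.fromisoformat(self.enrolment_date)
        if isinstance(self.end_date, str):
            self.end_date = date.fromisoformat(self.end_date)
        if self.enrolment_date > self.end_date:
            raise ValueError(
                f"{self.participant_id}: enrolment_date after end_date"
            )
        if self.regimen not in ("daily", "event_based"):
            raise ValueError(f"{self.participant_id}: unknown regimen {self.regimen!r}")


def read_meta(path, followups_path=None) -> list[ParticipantMeta]:
    """Read participant metadata (and optional follow-up self-reports) CSVs."""
    df = pd.read_csv(path)
    fus: dict[str, list] = {}
    if followups_path is not None and Path(followups_path).exists():
        fu = pd.read_csv(followups_path)
        for _, row in fu.iterrows():
            fus.setdefault(str(row["participant_id"]), []).append(
                (date.fromisoformat(str(row["date"])), str(row["selfreported_use_level"]))
            )
    return [
        ParticipantMeta(
            participant_id=str(r["participant_id"]),
            enrolment_date=str(r["enrolment_date"]),
            end_date=str(r["end_date"]),
            regimen=str(r.get("regimen", "daily")),
            followup_selfreports=sorted(fus.get(str(r["participant_id"]), [])),
        )
        for r in df.to_dict("records")
    ]


def events_to_daily_use(
    events: pd.DataFrame, meta: ParticipantMeta, day_cut_hour: int = 0
) -> pd.DataFrame:
    """Collapse timestamped cap openings to per-calendar-day dosing rows.

    One row per day of the observation window; ``dose_day`` is 1 iff at least
    one opening fell on that local calendar day, with ``opening_count``
    retained for misuse diagnostics.  The day boundary is midnight by default;
    ``day_cut_hour`` shifts it (e.g. 4 assigns a 02:00 opening to the previous
    day).  Events outside the window raise :class:`WindowError` naming them.
    """
    window = pd.date_range(meta.enrolment_date, meta.end_date, freq="D")
    counts = pd.Series(0, index=window.date, dtype=int)
    if len(events):
        ts = pd.to_datetime(events["timestamp"])
        event_days = (ts - pd.Timedelta(hours=day_cut_hour)).dt.date
        outside = (event_days < meta.enrolment_date) | (event_days > meta.end_date)
        if outside.any():
            bad = ", ".join(d.isoformat() for d in sorted(set(event_days[outside])))
            raise WindowError(
                f"{meta.participant_id}: {int(outside.sum())} event(s) outside "
                f"window {meta.enrolment_date}..{meta.end_date} on days [{bad}]"
            )
        vc = event_days.value_counts()
        counts.loc[vc.index] = vc.values
    return pd.DataFrame(
        {
            "date": window.date,
            "dose_day": (counts.values >= 1).astype(int),
            "opening_count": counts.values,
        }
    )


def surveys_to_daily_cas(surveys: pd.DataFrame) -> pd.DataFrame:
    """Unpack weekly surveys into per-day CAS rows (surveyed days only).

    Blank day slots (e.g. the tail of a final partial week) are skipped.
    Two surveys covering the same day for one participant raise
    :class:`OverlapError` naming the participant and dates.
    """
    rows = []
    for _, row in surveys.iterrows():
        pid = row["participant_id"]
        week_start = row["week_start"]
        if not isinstance(week_start, date) or isinstance(week_start, datetime):
            week_start = date.fromisoformat(str(week_start))
        for j in range(7):
            cas = row.get(f"day{j + 1}_cas")
            if pd.isna(cas):
                continue
            epi = row.get(f"day{j + 1}_episodes")
            par = row.get(f"day{j + 1}_partners")
            cas = int(cas)
            epi = cas if pd.isna(epi) else int(epi)
            par = cas if pd.isna(par) else int(par)
            if (cas == 0) != (epi == 0) or (cas == 0) != (par == 0):
                raise ValueError(
                    f"{pid} {week_start + timedelta(days=j)}: inconsistent "
                    f"cas/episode/partner triplet ({cas}, {epi}, {par})"
                )
            rows.append(
                {
                    "participant_id": pid,
                    "date": week_start + timedelta(days=j),
                    "cas_day": cas,
                    "episode_count": epi,
                    "partner_count": par,
                }
            )
    out = pd.DataFrame(rows, columns=["participant_id", "date", "cas_day", "episode_count", "partner_count"])
    dup = out.duplicated(subset=["participant_id", "date"], keep=False)
    if dup.any():
        bad = out[dup].sort_values(["participant_id", "date"])
        pairs = [f"{r.participant_id}@{r.date}" for r in bad.itertuples()][:10]
        raise OverlapError(f"overlapping surveys for participant-days: {pairs}")
    return out


def build_panel(
    daily_use: pd.DataFrame,
    daily_cas: pd.DataFrame,
    meta: ParticipantMeta,
    changepoint_date: date = CHANGEPOINT_DEFAULT,
) -> pd.DataFrame:
    """Merge one participant's dosing and CAS day-rows onto the t-axis."""
    window = pd.date_range(meta.enrolment_date, meta.end_date, freq="D")
    panel = pd.DataFrame({"date": window.date})
    panel["participant_id"] = meta.participant_id
    panel["t"] = (window - pd.Timestamp(changepoint_date)).days
    panel["pandemic"] = (panel["t"] >= 0).astype(int)

    use = daily_use.set_index("date")
    bad_use = [d for d in use.index if not (meta.enrolment_date <= d <= meta.end_date)]
    if bad_use:
        raise WindowError(
            f"{meta.participant_id}: daily-use rows outside window: {bad_use[:10]}"
        )
    panel["dose_day"] = panel["date"].map(use["dose_day"]).fillna(0).astype(int)
    panel["opening_count"] = panel["date"].map(use["opening_count"]).fillna(0).astype(int)
    panel["observed_dose"] = 1

    if len(daily_cas):
        cas = daily_cas[
            (daily_cas["participant_id"] == meta.participant_id)
            if "participant_id" in daily_cas.columns
            else slice(None)
        ]
        cas = cas.set_index("date")
        panel["cas_day"] = panel["date"].map(cas["cas_day"]).astype("Float64")
        panel["episode_count"] = panel["date"].map(cas["episode_count"]).astype("Float64")
        panel["partner_count"] = panel["date"].map(cas["partner_count"]).astype("Float64")
    else:
        panel["cas_day"] = pd.array([pd.NA] * len(panel), dtype="Float64")
        panel["episode_count"] = pd.array([pd.NA] * len(panel), dtype="Float64")
        panel["partner_count"] = pd.array([pd.NA] * len(panel), dtype="Float64")
    panel["observed_cas"] = panel["cas_day"].notna().astype(int)
    panel["excluded_sensitivity"] = 0
    return panel[PANEL_COLUMNS]


def build_cohort_panel(
    events: pd.DataFrame,
    surveys: pd.DataFrame,
    metas: list[ParticipantMeta],
    changepoint_date: date = CHANGEPOINT_DEFAULT,
    day_cut_hour: int = 0,
) -> pd.DataFrame:
    """Build and concatenate panels for a whole cohort."""
    daily_cas_all = surveys_to_daily_cas(surveys) if len(surveys) else pd.DataFrame(
        columns=["participant_id", "date", "cas_day", "episode_count", "partner_count"]
    )
    panels = []
    for meta in metas:
        ev = events[events["participant_id"] == meta.participant_id] if len(events) else events
        du = events_to_daily_use(ev, meta, day_cut_hour=day_cut_hour)
        dc = daily_cas_all[daily_cas_all["participant_id"] == meta.participant_id]
        panels.append(build_panel(du, dc, meta, changepoint_date))
    if not panels:
        return pd.DataFrame(columns=PANEL_COLUMNS)
    return pd.concat(panels, ignore_index=True)


def write_panel(panel: pd.DataFrame, path) -> None:
    out = panel.copy()
    out["date"] = out["date"].map(lambda d: d.isoformat())
    out.to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    panel = pd.read_csv(path)
    panel["date"] = panel["date"].map(date.fromisoformat)
    for col in ("cas_day", "episode_count", "partner_count"):
        panel[col] = panel[col].astype("Float64")
    for col in ("t", "pandemic", "dose_day", "opening_count", "observed_dose", "observed_cas", "excluded_sensitivity"):
        panel[col] = panel[col].astype(int)
    return panel[PANEL_COLUMNS]
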