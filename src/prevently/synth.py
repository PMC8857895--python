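"""Synthetic PrEP cohort generator.

Two layers are kept separate so that measurement error is itself measurable:

* the *truth* layer - per participant-day latent states (dose taken, CAS
  occurred, episode and partner counts) drawn from the same two-level
  logistic structure the analysis models assume: RCS time trends on a
  changepoint-centred axis, a step change at the changepoint, a bivariate
  normal (intercept, pandemic-indicator) random effect per participant, and
  a one-day-lag coupling from dosing to CAS;

* the *observation* layer - MEMS cap opening events and weekly surveys
  emitted from the truth, optionally contaminated by pocket doses, curiosity
  openings and non-monitored periods.

Everything is deterministic for a fixed :class:`~prevently.config.SimConfig`
(including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import Contamination, SimConfig
from .rcs import rcs_basis

__all__ = ["SyntheticCohort", "simulate_cohort", "emit_observations"]

# Self-reported PrEP-use levels offered at clinic follow-ups, with the
# percent-of-days each is taken to represent when screening for
# inconsistent MEMS use.
SELFREPORT_LEVELS = (
    (0.85, "daily"),
    (0.60, "most days"),
    (0.35, "about half"),
    (0.10, "occasionally"),
    (-1.0, "rarely or never"),
)
FOLLOWUP_SCHEDULE_DAYS = (90, 180, 270)


def _level_for_fraction(frac: float) -> str:
    for cut, label in SELFREPORT_LEVELS:
        if frac >= cut:
            return label
    return SELFREPORT_LEVELS[-1][1]


@dataclass
class SyntheticCohort:
    """Truth panel plus the observation tables emitted from it."""

    truth_panel: pd.DataFrame
    cap_events: pd.DataFrame
    weekly_surveys: pd.DataFrame
    participants: pd.DataFrame
    followups: pd.DataFrame
    config: SimConfig

    def write(self, outdir) -> dict[str, Path]:
        """Write every table as CSV (ISO-8601 dates); returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("truth_panel", "cap_events", "weekly_surveys", "participants", "followups"):
            path = outdir / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            paths[name] = path
        self.config.to_yaml(outdir / "sim_config.yaml")
        paths["sim_config"] = outdir / "sim_config.yaml"
        return paths


def _draw_windows(config: SimConfig, rng: np.random.Generator):
    """Enrolment dates uniform over the window; geometric withdrawal censoring."""
    lo, hi = config.enrolment_window
    span = (hi - lo).days + 1
    offsets = rng.integers(0, span, size=config.n_participants)
    enrol = [lo + timedelta(days=int(o)) for o in offsets]
    n_days = np.full(config.n_participants, config.followup_days, dtype=int)
    if config.withdrawal_hazard_per_day > 0:
        # day index (1-based) of withdrawal, geometric with the daily hazard
        w = rng.geometric(config.withdrawal_hazard_per_day, size=config.n_participants)
        n_days = np.minimum(n_days, w)
    return enrol, n_days


TRUTH_COLUMNS = [
    "participant_id",
    "date",
    "t",
    "pandemic",
    "latent_dose_taken",
    "latent_cas_day",
    "latent_episode_count",
    "latent_partner_count",
]


def simulate_truth(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the latent layer only: per participant-day truth plus metadata.

    Returns ``(truth_panel, participants)``; the truth panel already carries
    the changepoint-centred time ``t`` and the ``pandemic`` indicator so trend
    models can be fitted to it directly (recovery studies).
    """
    rng = np.random.default_rng(config.seed)
    fe = config.fixed_effects

    enrol, n_days = _draw_windows(config, rng)
    n = config.n_participants
    b_prep = _draw_re(config.re_cov_prep, n, rng)
    b_cas = _draw_re(config.re_cov_cas, n, rng)

    cols: dict[str, list] = {name: [] for name in TRUTH_COLUMNS}
    cp = config.changepoint_date.toordinal()
    for i in range(n):
        pid = f"P{i + 1:03d}"
        days = int(n_days[i])
        start = enrol[i].toordinal()
        t = np.arange(start - cp, start - cp + days)
        z = (t >= 0).astype(float)

        eta_prep = (
            fe.intercept_logit_prep
            + rcs_basis(t, config.prep_knots) @ np.asarray(fe.spline_coefs_prep)
            + fe.pandemic_log_or_prep * z
            + b_prep[i, 0]
            + b_prep[i, 1] * z
        )
        dose = rng.random(days) < expit(eta_prep)

        lagged = np.zeros(days)
        if days > config.lag_days:
            lagged[config.lag_days:] = dose[:-config.lag_days]
        eta_cas = (
            fe.intercept_logit_cas
            + rcs_basis(t, config.cas_knots) @ np.asarray(fe.spline_coefs_cas)
            + fe.pandemic_log_or_cas * z
            + fe.lag_log_or_prep_to_cas * lagged
            + b_cas[i, 0]
            + b_cas[i, 1] * z
        )
        cas = rng.random(days) < expit(eta_cas)

        episodes = np.zeros(days, dtype=int)
        partners = np.zeros(days, dtype=int)
        n_cas = int(cas.sum())
        if n_cas:
            episodes[cas] = rng.choice([1, 2, 3], size=n_cas, p=config.episode_count_probs)
            partners[cas] = rng.choice([1, 2], size=n_cas, p=config.partner_count_probs)

        cols["participant_id"].append(np.repeat(pid, days))
        cols["date"].append([date.fromordinal(o) for o in range(start, start + days)])
        cols["t"].append(t)
        cols["pandemic"].append(z.astype(int))
        cols["latent_dose_taken"].append(dose.astype(int))
        cols["latent_cas_day"].append(cas.astype(int))
        cols["latent_episode_count"].append(episodes)
        cols["latent_partner_count"].append(partners)

    if n:
        truth = pd.DataFrame(
            {name: np.concatenate(vals) for name, vals in cols.items()}
        )
    else:
        truth = pd.DataFrame(columns=TRUTH_COLUMNS)

    participants = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:03d}" for i in range(n)],
            "enrolment_date": [d.isoformat() for d in enrol],
            "end_date": [
                (enrol[i] + timedelta(days=int(n_days[i]) - 1)).isoformat() for i in range(n)
            ],
            "regimen": "daily",
        }
    )
    return truth, participants


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort (truth and observations) from ``config``."""
    truth, participants = simulate_truth(config)
    rng = np.random.default_rng(config.seed)
    rng = np.random.default_rng(rng.integers(0, 2**31 - 1, size=2)[1])
    obs_seed = int(rng.integers(0, 2**31 - 1)) if config.n_participants else 0
    cap_events, weekly_surveys = emit_observations(truth, config.contamination, obs_seed)
    followups = _followup_selfreports(truth, participants)
    return SyntheticCohort(truth, cap_events, weekly_surveys, participants, followups, config)


def _draw_re(cov: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return np.zeros((0, 2))
    # eigen square root tolerates semi-definite (including zero) covariances
    w, v = np.linalg.eigh(cov)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
    return rng.standard_normal((n, 2)) @ root.T


def _followup_selfreports(truth: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Clinic follow-up self-reports of PrEP use, faithful to the latent truth.

    Each report covers the interval since the previous one; the reported level
    is the category containing the latent percent of dose-days, so any gap
    between self-report and MEMS-derived use reflects observation-layer
    contamination only.
    """
    rows = []
    for _, meta in participants.iterrows():
        pid = meta["participant_id"]
        sub = truth[truth["participant_id"] == pid]
        if sub.empty:
            continue
        enrol = date.fromisoformat(meta["enrolment_date"])
        end = date.fromisoformat(meta["end_date"])
        prev = enrol
        for k in FOLLOWUP_SCHEDULE_DAYS:
            fu_date = min(enrol + timedelta(days=k), end)
            mask = (sub["date"] > prev) & (sub["date"] <= fu_date) if prev != enrol else (
                (sub["date"] >= prev) & (sub["date"] <= fu_date)
            )
            seg = sub[mask]
            if len(seg):
                frac = seg["latent_dose_taken"].mean()
                rows.append(
                    {
                        "participant_id": pid,
                        "date": fu_date.isoformat(),
                        "selfreported_use_level": _level_for_fraction(float(frac)),
                    }
                )
            prev = fu_date
            if fu_date >= end:
                break
    return pd.DataFrame(rows, columns=["participant_id", "date", "selfreported_use_level"])


def emit_observations(
    truth_panel: pd.DataFrame, contamination: Contamination | dict, seed: int
):
    """Emit MEMS cap events and weekly surveys from a latent truth panel.

    Every latent dose-day produces one cap event (at a random daytime hour)
    unless suppressed by a pocket-dose draw or because it falls in a
    non-monitored period; curiosity openings add events on non-dose days.
    Weekly surveys report the latent CAS fields faithfully for every observed
    day (full response).  Deterministic for a fixed seed.
    """
    if isinstance(contamination, dict):
        contamination = Contamination(**contamination)
    contamination.validate()
    rng = np.random.default_rng(seed)

    event_rows = []
    survey_rows = []
    day_cols = [
        c
        for trio in (
            (f"day{j}_cas", f"day{j}_episodes", f"day{j}_partners") for j in range(1, 8)
        )
        for c in trio
    ]
    for pid, sub in truth_panel.groupby("participant_id", sort=True):
        sub = sub.sort_values("date").reset_index(drop=True)
        days = len(sub)
        dose = sub["latent_dose_taken"].to_numpy(dtype=bool)

        monitored = np.ones(days, dtype=bool)
        if contamination.p_nonmonitored_period > 0 and rng.random() < contamination.p_nonmonitored_period:
            length = min(contamination.nonmonitored_length_days, days)
            start = int(rng.integers(0, days - length + 1))
            monitored[start : start + length] = False

        pocket = rng.random(days) < contamination.p_pocket_dose_per_day
        curiosity = rng.random(days) < contamination.p_curiosity_open_per_day
        emits = monitored & ((dose & ~pocket) | curiosity)

        hours = rng.integers(6, 24, size=days)
        minutes = rng.integers(0, 60, size=days)
        for idx in np.flatnonzero(emits):
            d = sub.at[idx, "date"]
            event_rows.append(
                {
                    "participant_id": pid,
                    "timestamp": f"{d.isoformat()}T{hours[idx]:02d}:{minutes[idx]:02d}:00",
                }
            )

        # weekly surveys anchored at enrolment; the final survey may cover a
        # partial week (out-of-window slots left blank)
        for start in range(0, days, 7):
            week = sub.iloc[start : start + 7]
            row = {
                "participant_id": pid,
                "week_start": week.iloc[0]["date"].isoformat(),
            }
            for j in range(7):
                if j < len(week):
                    row[f"day{j + 1}_cas"] = int(week.iloc[j]["latent_cas_day"])
                    row[f"day{j + 1}_episodes"] = int(week.iloc[j]["latent_episode_count"])
                    row[f"day{j + 1}_partners"] = int(week.iloc[j]["latent_partner_count"])
                else:
                    row[f"day{j + 1}_cas"] = pd.NA
                    row[f"day{j + 1}_episodes"] = pd.NA
                    row[f"day{j + 1}_partners"] = pd.NA
            survey_rows.append(row)

    cap_events = pd.DataFrame(event_rows, columns=["participant_id", "timestamp"])
    weekly_surveys = pd.DataFrame(survey_rows, columns=["participant_id", "week_start"] + day_cols)
    return cap_events, weekly_surveys
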