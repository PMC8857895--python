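"""Simulation configuration for the synthetic PrEP cohort.

The defaults encode the cohort the analysis was designed for: ~60 MSM PrEP
users enrolled over autumn 2019 - January 2020, each followed for about nine
months of daily electronic dosing data across the 2020-03-16 changepoint when
UK COVID-19 control measures began.  Effect sizes default to the fitted
quantities from that cohort (pandemic odds ratios 0.44 for dosing and 0.35
for condomless anal sex, a 1.93 odds ratio linking previous-day dosing to
today's CAS, and an unstructured intercept/pandemic-indicator random-effect
covariance of 4.47/3.75 with covariance -1.55 on the logit scale for dosing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, datetime
import math

import numpy as np
import yaml

__all__ = ["ConfigError", "FixedEffects", "Contamination", "SimConfig"]

CHANGEPOINT_DEFAULT = date(2020, 3, 16)

# Default fitting knots (days relative to the changepoint): four for the
# dosing model, five for the sexual-behaviour models.
PREP_KNOTS_DEFAULT = (-126.0, -24.0, 64.0, 184.0)
CAS_KNOTS_DEFAULT = (-122.0, -39.0, 23.0, 91.0, 188.0)


class ConfigError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


def _as_date(x) -> date:
    if isinstance(x, datetime):
        return x.date()
    if isinstance(x, date):
        return x
    return date.fromisoformat(str(x))


@dataclass
class FixedEffects:
    """Population-level coefficients of the two daily Bernoulli processes.

    Intercepts are on the conditional (median-participant) logit scale at
    t = 0; spline coefficients multiply the RCS basis of days since the
    changepoint; the pandemic terms are log odds ratios for the I(t >= 0)
    indicator; the lag term couples yesterday's dose to today's CAS odds.
    """

    intercept_logit_prep: float = 0.85   # ~= logit(0.70)
    intercept_logit_cas: float = -2.38   # ~= logit(0.085)
    spline_coefs_prep: tuple[float, ...] = (-0.0055, 0.0, 0.0)
    spline_coefs_cas: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    pandemic_log_or_prep: float = math.log(0.44)
    pandemic_log_or_cas: float = math.log(0.35)
    lag_log_or_prep_to_cas: float = math.log(1.93)


@dataclass
class Contamination:
    """Observation-level MEMS misuse processes.

    pocket doses: the pill is taken but the monitored bottle never opened
    (dose-day emits no event); curiosity openings: the cap is opened on a
    day with no dose; non-monitored periods: a contiguous stretch where the
    cap is not used at all (e.g. decanted pills, travel) so no events are
    recorded regardless of the latent dosing.
    """

    p_curiosity_open_per_day: float = 0.0
    p_pocket_dose_per_day: float = 0.0
    p_nonmonitored_period: float = 0.0
    nonmonitored_length_days: int = 28

    def validate(self) -> None:
        for name in ("p_curiosity_open_per_day", "p_pocket_dose_per_day", "p_nonmonitored_period"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.nonmonitored_length_days < 1:
            raise ConfigError("nonmonitored_length_days must be >= 1")


def _check_probs(name: str, probs, n: int) -> tuple[float, ...]:
    probs = tuple(float(p) for p in probs)
    if len(probs) != n:
        raise ConfigError(f"{name} must have {n} entries, got {len(probs)}")
    if any(p < 0 or p > 1 for p in probs):
        raise ConfigError(f"{name} entries must be in [0, 1], got {probs}")
    if abs(sum(probs) - 1.0) > 1e-8:
        raise ConfigError(f"{name} must sum to 1, got sum {sum(probs)}")
    return probs


def _check_psd(name: str, mat) -> np.ndarray:
    m = np.asarray(mat, dtype=float)
    if m.shape != (2, 2):
        raise ConfigError(f"{name} must be 2x2, got shape {m.shape}")
    if abs(m[0, 1] - m[1, 0]) > 1e-10:
        raise ConfigError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(m).min() < -1e-10:
        raise ConfigError(f"{name} must be positive semi-definite, got {m.tolist()}")
    return m


@dataclass
class SimConfig:
    n_participants: int = 60
    enrolment_window: tuple[date, date] = (date(2019, 9, 24), date(2020, 1, 27))
    followup_days: int = 270
    changepoint_date: date = CHANGEPOINT_DEFAULT
    fixed_effects: FixedEffects = field(default_factory=FixedEffects)
    # Unstructured covariance of (random intercept, random pandemic-indicator
    # slope) on the logit scale, for the dosing process.
    re_covariance: tuple = ((4.47, -1.55), (-1.55, 3.75))
    # Same structure for the CAS process (drawn independently).
    re_covariance_cas: tuple = ((1.02, 0.06), (0.06, 1.03))
    # Conditional distributions given a CAS day: episodes {1, 2, 3+} and
    # partners {1, 2+}; chosen so the implied per-day means match the
    # pre-changepoint cohort (0.17 episodes/day, 0.14 partners/day at a 9%
    # daily CAS rate, i.e. ~1.87 episodes and ~1.54 partners per CAS day).
    episode_count_probs: tuple[float, float, float] = (0.44, 0.25, 0.31)
    partner_count_probs: tuple[float, float] = (0.46, 0.54)
    contamination: Contamination = field(default_factory=Contamination)
    # ~10% attrition over 270 days: 1 - 0.9**(1/270).
    withdrawal_hazard_per_day: float = 3.9e-4
    seed: int = 0
    # Knots used by the simulator's spline contributions (spline_coefs_* must
    # have len(knots) - 1 entries each).
    prep_knots: tuple[float, ...] = PREP_KNOTS_DEFAULT
    cas_knots: tuple[float, ...] = CAS_KNOTS_DEFAULT
    lag_days: int = 1

    def __post_init__(self) -> None:
        self.enrolment_window = tuple(_as_date(d) for d in self.enrolment_window)
        self.changepoint_date = _as_date(self.changepoint_date)
        if isinstance(self.fixed_effects, dict):
            self.fixed_effects = FixedEffects(**self.fixed_effects)
        if isinstance(self.contamination, dict):
            self.contamination = Contamination(**self.contamination)
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        lo, hi = self.enrolment_window
        if hi < lo:
            raise ConfigError("enrolment_window must be (start, end) with start <= end")
        if self.followup_days < 1:
            raise ConfigError("followup_days must be >= 1")
        if self.changepoint_date < lo:
            raise ConfigError(
                "changepoint_date must lie inside or after the enrolment window"
            )
        _check_psd("re_covariance", self.re_covariance)
        _check_psd("re_covariance_cas", self.re_covariance_cas)
        _check_probs("episode_count_probs", self.episode_count_probs, 3)
        _check_probs("partner_count_probs", self.partner_count_probs, 2)
        self.contamination.validate()
        if not 0.0 <= self.withdrawal_hazard_per_day <= 1.0:
            raise ConfigError("withdrawal_hazard_per_day must be in [0, 1]")
        if self.lag_days < 1:
            raise ConfigError("lag_days must be >= 1")
        fe = self.fixed_effects
        if len(fe.spline_coefs_prep) != len(self.prep_knots) - 1:
            raise ConfigError(
                f"spline_coefs_prep needs {len(self.prep_knots) - 1} entries"
            )
        if len(fe.spline_coefs_cas) != len(self.cas_knots) - 1:
            raise ConfigError(
                f"spline_coefs_cas needs {len(self.cas_knots) - 1} entries"
            )

    @property
    def re_cov_prep(self) -> np.ndarray:
        return np.asarray(self.re_covariance, dtype=float)

    @property
    def re_cov_cas(self) -> np.ndarray:
        return np.asarray(self.re_covariance_cas, dtype=float)

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["enrolment_window"] = [x.isoformat() for x in self.enrolment_window]
        d["changepoint_date"] = self.changepoint_date.isoformat()
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
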