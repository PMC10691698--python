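"""Domain types and calendar conventions for ED occupancy modelling.

The basic time unit is the *weekly hour*: hour 0 is Sunday 07:00 (the start
of the Israeli workweek and of the morning shift), hour 167 is the last hour
before the following Sunday 07:00.  Days switch at 07:00, so "Sunday" covers
Sunday 07:00 -- Monday 07:00.  Shifts are morning 07:00-15:00, afternoon
15:00-23:00 and night 23:00-07:00; each day therefore holds exactly three
8-hour shifts starting at within-day offsets 0, 8 and 16.

Exit rates are piecewise constant over four day groups -- Sunday, midweek
(Monday-Thursday), Friday and Saturday -- reflecting the weekly staffing and
case-mix cycle of an Israeli emergency department.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import yaml

WEEK_HOURS = 168
SHIFT_HOURS = 8
SHIFT_NAMES = ("morning", "afternoon", "night")
DAY_NAMES = ("Sunday", "Monday", "Tuesday", "Wednesday", "Thursday",
             "Friday", "Saturday")

DAY_GROUPS = ("Sunday", "Midweek", "Friday", "Saturday")
#: day-of-week index (0 = Sunday) -> day group
DAY_TO_GROUP = ("Sunday", "Midweek", "Midweek", "Midweek", "Midweek",
                "Friday", "Saturday")
#: number of days each group contributes to a week (Sun, Mon-Thu, Fri, Sat)
DAY_GROUP_WEIGHTS = {"Sunday": 1, "Midweek": 4, "Friday": 1, "Saturday": 1}


def weekly_hour_of(t: float | np.ndarray) -> np.ndarray:
    """Map hours-since-week-epoch onto the periodic weekly hour [0, 168)."""
    return np.asarray(t) % WEEK_HOURS


def day_group_of_hour(weekly_hour: float | np.ndarray) -> np.ndarray:
    """Day group label for each weekly hour (days switch at 07:00)."""
    day = (np.asarray(weekly_hour, dtype=float) // 24).astype(int) % 7
    return np.asarray(DAY_TO_GROUP, dtype=object)[day]


def shift_of_hour(weekly_hour: float | np.ndarray) -> np.ndarray:
    """Shift label ('morning'/'afternoon'/'night') for each weekly hour."""
    offset = (np.asarray(weekly_hour, dtype=float) % 24 // SHIFT_HOURS).astype(int)
    return np.asarray(SHIFT_NAMES, dtype=object)[offset]


@dataclass(frozen=True)
class ModelParams:
    """Exit rates per day group and the two noise magnitudes.

    Parameters
    ----------
    beta_by_daygroup
        Per-patient exit rate (1/hour) for each of the four day groups;
        1/beta is the typical length of stay.
    sigma1
        Magnitude of the demographic (inter-individual) noise.  The value 1
        corresponds to pure Poisson arrivals and exits; values above 1 allow
        for extra heterogeneity between individuals.
    sigma2
        Magnitude of the systematic (environmental) noise that multiplies
        the exit rate of everyone present at once.
    """

    beta_by_daygroup: Mapping[str, float]
    sigma1: float = 1.0
    sigma2: float = 0.0

    def __post_init__(self) -> None:
        missing = set(DAY_GROUPS) - set(self.beta_by_daygroup)
        if missing:
            raise ValueError(f"missing day groups: {sorted(missing)}")
        if any(b <= 0 for b in self.beta_by_daygroup.values()):
            raise ValueError("all exit rates beta must be positive")
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError("noise magnitudes must be non-negative")

    def beta_hourly(self) -> np.ndarray:
        """Exit rate at each of the 168 weekly hours."""
        groups = day_group_of_hour(np.arange(WEEK_HOURS))
        return np.array([self.beta_by_daygroup[g] for g in groups])

    def beta_at(self, t: float | np.ndarray) -> np.ndarray:
        """Exit rate at time t (hours since week epoch), periodic weekly."""
        return self.beta_hourly()[np.floor(weekly_hour_of(t)).astype(int)]

    def mean_beta(self) -> float:
        """Day-weighted mean exit rate (weights 1,4,1,1 over the week)."""
        total = sum(DAY_GROUP_WEIGHTS[g] * self.beta_by_daygroup[g]
                    for g in DAY_GROUPS)
        return total / sum(DAY_GROUP_WEIGHTS.values())

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)


def reference_params(sigma1: float = 1.1, sigma2: float = 0.36) -> ModelParams:
    """Parameters estimated from five years of records of a large Israeli
    hospital ED: exit rates per day group and the two noise magnitudes.

    The midweek turnover is faster on the weekend (beta_Sat > beta_Sun)
    while Sunday, the busiest day, has the slowest exit rate.
    """
    return ModelParams(
        beta_by_daygroup={"Sunday": 0.224, "Midweek": 0.244,
                          "Friday": 0.280, "Saturday": 0.304},
        sigma1=sigma1,
        sigma2=sigma2,
    )


@dataclass(frozen=True)
class WeeklyArrivalProfile:
    """Deterministic arrival flux f(t): patients/hour at each weekly hour.

    The flux is piecewise constant over hourly bins [h, h+1) and extends
    periodically beyond one week.  ``week_epoch`` records the calendar
    convention anchor (Sunday 07:00) for documentation and CSV round trips.
    """

    hourly_flux: np.ndarray
    week_epoch: str = "Sunday 07:00"

    def __post_init__(self) -> None:
        flux = np.asarray(self.hourly_flux, dtype=float)
        if flux.shape != (WEEK_HOURS,):
            raise ValueError(f"profile must hold {WEEK_HOURS} hourly values")
        if np.any(flux < 0) or not np.all(np.isfinite(flux)):
            raise ValueError("arrival flux must be finite and non-negative")
        object.__setattr__(self, "hourly_flux", flux)

    def flux_at(self, t: float | np.ndarray) -> np.ndarray:
        """f(t) for t in hours since week epoch (periodic)."""
        return self.hourly_flux[np.floor(weekly_hour_of(t)).astype(int)]

    @property
    def mean(self) -> float:
        return float(self.hourly_flux.mean())

    @property
    def std(self) -> float:
        return float(self.hourly_flux.std())

    def scaled(self, factor: float) -> "WeeklyArrivalProfile":
        """Uniformly rescaled profile (e.g. for elasticity scans)."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return WeeklyArrivalProfile(self.hourly_flux * factor, self.week_epoch)


@dataclass(frozen=True)
class TrapezoidDayShape:
    """One day's arrival flux as a trapezoid: a quiet night level, a linear
    morning ramp up to a daytime plateau, and a linear evening ramp back down.

    Breakpoints are hour offsets within the day, measured from the day start
    at 07:00 (so offset 0 = 07:00, offset 17 = midnight).  The defaults give
    the typical ED arrival curve: a steep rise from 08:00, a late-morning to
    mid-afternoon peak (10:00-16:00), a decline through the evening, and an
    overnight trough from about 01:00.
    """

    night_level: float
    day_level: float
    ramp_up_start: float = 1.0    # 08:00
    plateau_start: float = 3.0    # 10:00
    ramp_down_start: float = 9.0  # 16:00
    night_start: float = 18.0     # 01:00

    def __post_init__(self) -> None:
        if self.night_level < 0 or self.day_level < 0:
            raise ValueError("flux levels must be non-negative")
        knots = (self.ramp_up_start, self.plateau_start,
                 self.ramp_down_start, self.night_start)
        if not all(0 <= a <= b <= 24 for a, b in zip(knots, knots[1:])):
            raise ValueError("breakpoints must be ordered within the 24-h day")

    def value_at(self, offset: float | np.ndarray) -> np.ndarray:
        """Flux at a within-day hour offset (piecewise linear)."""
        o = np.asarray(offset, dtype=float)
        xp = [0.0, self.ramp_up_start, self.plateau_start,
              self.ramp_down_start, self.night_start, 24.0]
        fp = [self.night_level, self.night_level, self.day_level,
              self.day_level, self.night_level, self.night_level]
        return np.interp(o, xp, fp)

    def hourly_values(self) -> np.ndarray:
        """Average flux over each of the 24 hourly bins of the day."""
        # piecewise linear, so a fine midpoint quadrature is exact enough
        grid = np.linspace(0, 24, 24 * 60, endpoint=False) + 0.5 / 60
        return self.value_at(grid).reshape(24, 60).mean(axis=1)


@dataclass
class SimulationConfig:
    """Bundle of everything a forward simulation needs, YAML round-trippable."""

    params: ModelParams
    profile: WeeklyArrivalProfile
    dt: float = 0.01
    horizon: float = float(WEEK_HOURS)
    n_realizations: int = 10_000
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "beta_by_daygroup": dict(self.params.beta_by_daygroup),
            "sigma1": self.params.sigma1,
            "sigma2": self.params.sigma2,
            "hourly_flux": [float(v) for v in self.profile.hourly_flux],
            "week_epoch": self.profile.week_epoch,
            "dt": self.dt,
            "horizon": self.horizon,
            "n_realizations": self.n_realizations,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        params = ModelParams(beta_by_daygroup=dict(d["beta_by_daygroup"]),
                             sigma1=float(d.get("sigma1", 1.0)),
                             sigma2=float(d.get("sigma2", 0.0)))
        profile = WeeklyArrivalProfile(np.asarray(d["hourly_flux"], dtype=float),
                                       d.get("week_epoch", "Sunday 07:00"))
        return cls(params=params, profile=profile,
                   dt=float(d.get("dt", 0.01)),
                   horizon=float(d.get("horizon", WEEK_HOURS)),
                   n_realizations=int(d.get("n_realizations", 10_000)),
                   seed=int(d.get("seed", 0)))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
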