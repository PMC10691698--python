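"""Synthetic ED visit logs with the statistical structure of a large
Israeli hospital emergency department.

The generator is agent-level: every synthetic patient has an arrival and a
departure timestamp at minute resolution, so every downstream stage (metrics,
estimation, analysis) runs on visit logs exactly as it would on real records.

Statistical targets emulated by the default (reference) study:

* hourly arrival flux with mean 14 and STD 8 patients/hour over the week,
  following a trapezoid day shape (quiet night, daytime plateau) with busy
  weekdays (Sunday-Thursday) and quiet weekends (Friday-Saturday);
* exponential length of stay with day-group exit rates (mean ~3.9 h);
* hourly occupancy with mean 55 and STD 27 patients;
* both noise channels of the Langevin model: demographic noise of magnitude
  sigma1 and systematic exit-rate noise of magnitude sigma2.

Systematic noise is realized as an hourly-refreshed multiplier 1 + eps_k on
the exit rate, shared by everyone present (eps_k ~ N(0, sigma2), clamped so
the rate stays non-negative) -- the agent-level counterpart of white noise
that equally influences all individuals, at 1-hour resolution.

Demographic noise beyond the intrinsic Poisson level (sigma1 > 1) is realized
by compound arrivals: arrival events carry batch sizes 1 + Poisson(lambda_b),
with lambda_b chosen hour by hour so the total demographic noise intensity
matches sigma1^2 (f + beta*n) from the Langevin model.  At sigma1 = 1 the
batches degenerate to size 1 and arrivals are a pure nonhomogeneous Poisson
process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import langevin_hourly_matrix, mean_field_weekly
from .params import (WEEK_HOURS, ModelParams, TrapezoidDayShape,
                     WeeklyArrivalProfile)

__all__ = [
    "VisitRecord", "VisitLog", "CalibrationError",
    "build_reference_profile", "calibrate_profile", "generate_visit_log",
    "reference_profile", "write_visit_log", "read_visit_log",
    "DEFAULT_TARGETS",
]

#: printed crowding moments of the reference ED (patients/hour and patients)
DEFAULT_TARGETS = {"flux_mean": 14.0, "flux_std": 8.0,
                   "occ_mean": 55.0, "occ_std": 27.0}

#: default calendar anchor: a Sunday 07:00
DEFAULT_EPOCH = pd.Timestamp("2013-01-06 07:00")


@dataclass(frozen=True)
class VisitRecord:
    """A single ED visit: opaque id plus arrival/departure timestamps."""

    visit_id: str
    arrival_ts: pd.Timestamp
    departure_ts: pd.Timestamp

    def __post_init__(self) -> None:
        if self.departure_ts <= self.arrival_ts:
            raise ValueError("departure must be after arrival")


@dataclass
class VisitLog:
    """A collection of visits over [period_start, period_start + n_weeks).

    Arrival/departure times are kept internally as fractional hours since
    ``period_start`` (which is always a Sunday 07:00, the week epoch), at
    minute resolution; timestamps are materialized on demand.  Records are
    sorted by arrival.  Departures may extend past the period end: stays in
    progress at the end of the observation window run to completion rather
    than being truncated.
    """

    arrivals_h: np.ndarray
    departures_h: np.ndarray
    period_start: pd.Timestamp = DEFAULT_EPOCH
    n_weeks: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.arrivals_h, dtype=float)
        d = np.asarray(self.departures_h, dtype=float)
        if a.shape != d.shape or a.ndim != 1:
            raise ValueError("arrival and departure arrays must match")
        if np.any(d <= a):
            raise ValueError("every departure must be after its arrival")
        if a.size and (a.min() < 0 or a.max() >= self.period_hours):
            raise ValueError("arrivals must fall within the log period")
        if np.any(np.diff(a) < 0):
            order = np.argsort(a, kind="stable")
            a, d = a[order], d[order]
        self.arrivals_h = a
        self.departures_h = d

    @property
    def period_hours(self) -> float:
        return self.n_weeks * WEEK_HOURS

    @property
    def period_end(self) -> pd.Timestamp:
        return self.period_start + pd.Timedelta(hours=self.period_hours)

    def __len__(self) -> int:
        return self.arrivals_h.size

    def to_frame(self) -> pd.DataFrame:
        """Records as a DataFrame with ISO timestamps at minute precision."""
        arr = self.period_start + pd.to_timedelta(
            np.rint(self.arrivals_h * 60).astype(np.int64), unit="m")
        dep = self.period_start + pd.to_timedelta(
            np.rint(self.departures_h * 60).astype(np.int64), unit="m")
        ids = [f"v{i:07d}" for i in range(len(self))]
        return pd.DataFrame({"visit_id": ids, "arrival_ts": arr,
                             "departure_ts": dep})

    def records(self) -> list[VisitRecord]:
        frame = self.to_frame()
        return [VisitRecord(r.visit_id, r.arrival_ts, r.departure_ts)
                for r in frame.itertuples(index=False)]


class CalibrationError(RuntimeError):
    """Raised when no profile in the trapezoid family meets the targets."""

    def __init__(self, message: str, residuals: dict | None = None):
        super().__init__(message)
        self.residuals = residuals or {}


def build_reference_profile(weekday_shape: TrapezoidDayShape,
                            weekend_shape: TrapezoidDayShape
                            ) -> WeeklyArrivalProfile:
    """Weekly profile: weekday trapezoid Sunday-Thursday, weekend trapezoid
    Friday-Saturday (days anchored at 07:00)."""
    wd = weekday_shape.hourly_values()
    we = weekend_shape.hourly_values()
    flux = np.concatenate([np.tile(wd, 5), np.tile(we, 2)])
    return WeeklyArrivalProfile(flux)


_UNIT_SHAPE = TrapezoidDayShape(night_level=0.0, day_level=1.0).hourly_values()


def _family_profile(base: float, amp: float, weekend_scale: float
                    ) -> WeeklyArrivalProfile:
    """Calibration family: a shared night level `base` for every day of the
    week plus a daytime trapezoid bump of height `amp` on weekdays, scaled
    by ``weekend_scale`` on Friday-Saturday.  Overnight emergencies do not
    follow the workweek, so the weekend dip applies to the daytime component
    only."""
    wd = TrapezoidDayShape(night_level=base, day_level=base + amp)
    we = TrapezoidDayShape(night_level=base,
                           day_level=base + weekend_scale * amp)
    return build_reference_profile(wd, we)


def _solve_shape(weekend_scale: float, flux_mean: float,
                 flux_std: float) -> tuple[float, float]:
    """(base, amp) so the weekly profile has the requested pooled hourly
    flux mean and STD, at the given weekend/weekday scale."""
    from scipy.optimize import brentq

    g_mean = float(_UNIT_SHAPE.mean())
    s = weekend_scale
    day_weight = g_mean * (5.0 + 2.0 * s) / 7.0  # mean of the bump per week

    def base_for(amp: float) -> float:
        return max(flux_mean - amp * day_weight, 0.0)

    def pooled_std(amp: float) -> float:
        return _family_profile(base_for(amp), amp, s).std

    amp_max = flux_mean / day_weight  # keeps the night level non-negative
    lo, hi = pooled_std(0.0), pooled_std(amp_max)
    if not (lo <= flux_std <= hi):
        raise CalibrationError(
            f"flux STD {flux_std} outside the reachable range "
            f"[{lo:.2f}, {hi:.2f}] at weekend scale {s:.2f}",
            {"flux_std_lo": lo, "flux_std_hi": hi})
    amp = brentq(lambda a: pooled_std(a) - flux_std, 0.0, amp_max, xtol=1e-10)
    return base_for(amp), amp


def _occupancy_moments(profile: WeeklyArrivalProfile, params: ModelParams,
                       seed: int, n_realizations: int,
                       burn_in: int = 48) -> tuple[float, float]:
    """Pooled mean/STD of hourly occupancy over one simulated week
    (common random numbers: a fresh generator from `seed` each call)."""
    rng = np.random.default_rng(seed)
    n0 = mean_field_weekly(profile, params).counts[-burn_in % WEEK_HOURS]
    _, counts = langevin_hourly_matrix(profile, params, n0,
                                       horizon=burn_in + WEEK_HOURS, dt=0.01,
                                       n_realizations=n_realizations, rng=rng,
                                       t_start=float(-burn_in))
    week = counts[:, burn_in + 1:]
    return float(week.mean()), float(week.std())


def calibrate_profile(params: ModelParams, targets: dict | None = None,
                      seed: int = 0, n_realizations: int = 1000
                      ) -> WeeklyArrivalProfile:
    """Trapezoid weekly arrival profile calibrated to the printed crowding
    moments: hourly flux mean/STD across the 168 weekly hours, and the
    mean/STD of the hourly occupancy the profile induces under `params`.

    The search is deterministic given `seed` (common random numbers across
    all candidate profiles).  Three knobs are tuned: the trapezoid base and
    amplitude (solved analytically for the flux moments) and the
    weekend/weekday scale (bisection on the simulated occupancy STD, which
    grows as weekend contrast moves flux variance to low frequencies that
    the exit-rate filter passes).  A final uniform rescale, confined to the
    flux-mean tolerance band, centres the occupancy mean.

    Raises :class:`CalibrationError` with the best residuals if the targets
    are unreachable within the shape family.
    """
    from scipy.optimize import brentq

    t = dict(DEFAULT_TARGETS, **(targets or {}))
    if min(t.values()) < 0 or t["flux_mean"] <= 0 or t["occ_mean"] <= 0:
        raise ValueError("targets must be positive (STDs non-negative)")

    if t["flux_std"] == 0:
        # flat profile: the mean-field inversion f = occ_mean * beta_bar,
        # clamped to the flux-mean tolerance band
        level = float(np.clip(t["occ_mean"] * params.mean_beta(),
                              0.98 * t["flux_mean"], 1.02 * t["flux_mean"]))
        return WeeklyArrivalProfile(np.full(WEEK_HOURS, level))

    def moments_at(weekend_scale: float) -> tuple[WeeklyArrivalProfile, float, float]:
        base, amp = _solve_shape(weekend_scale, t["flux_mean"], t["flux_std"])
        profile = _family_profile(base, amp, weekend_scale)
        mean0, _ = _occupancy_moments(profile, params, seed, n_realizations)
        scale = float(np.clip(t["occ_mean"] / mean0, 0.98, 1.02))
        profile = profile.scaled(scale)
        mean1, std1 = _occupancy_moments(profile, params, seed, n_realizations)
        return profile, mean1, std1

    lo_s, hi_s = 0.15, 0.95
    _, _, std_lo = moments_at(lo_s)   # most weekend contrast -> largest STD
    _, _, std_hi = moments_at(hi_s)
    target_std = t["occ_std"]
    if not (min(std_lo, std_hi) <= target_std <= max(std_lo, std_hi)):
        raise CalibrationError(
            f"occupancy STD {target_std} outside reachable range "
            f"[{min(std_lo, std_hi):.2f}, {max(std_lo, std_hi):.2f}]",
            {"occ_std_lo": std_lo, "occ_std_hi": std_hi})
    s_star = brentq(lambda s: moments_at(s)[2] - target_std, lo_s, hi_s,
                    xtol=2e-3)
    profile, occ_mean, occ_std = moments_at(s_star)

    residuals = {
        "flux_mean": profile.mean / t["flux_mean"] - 1.0,
        "flux_std": profile.std / t["flux_std"] - 1.0,
        "occ_mean": occ_mean / t["occ_mean"] - 1.0,
        "occ_std": occ_std / t["occ_std"] - 1.0,
    }
    bands = {"flux_mean": 0.02, "flux_std": 0.10,
             "occ_mean": 0.03, "occ_std": 0.10}
    bad = {k: v for k, v in residuals.items() if abs(v) > bands[k] + 1e-6}
    if bad:
        raise CalibrationError(f"calibration residuals out of band: {bad}",
                               residuals)
    return profile


def reference_profile(params: ModelParams | None = None, seed: int = 0,
                      n_realizations: int = 1000) -> WeeklyArrivalProfile:
    """The calibrated reference-study profile (default targets, reference
    parameters)."""
    from .params import reference_params
    return calibrate_profile(params or reference_params(), seed=seed,
                             n_realizations=n_realizations)


def _batch_rate(profile: WeeklyArrivalProfile, params: ModelParams
                ) -> np.ndarray:
    """Per-weekly-hour mean extra batch size lambda_b realizing sigma1.

    The arrival Fano factor needed so total demographic noise matches
    sigma1^2 (f + beta nbar) hour by hour is
        F = sigma1^2 + (sigma1^2 - 1) * beta * nbar / f,
    and a compound Poisson with batches 1 + Poisson(lambda_b) has Fano
    factor m + lambda_b/m with m = 1 + lambda_b, giving
        m = [(F - 1) + sqrt((F - 1)^2 + 4)] / 2.
    sigma1 < 1 (sub-Poisson arrivals) is not representable by batching and
    is clamped to the Poisson level F = 1.
    """
    f = profile.hourly_flux
    beta = params.beta_hourly()
    nbar = mean_field_weekly(profile, params).counts
    with np.errstate(divide="ignore", invalid="ignore"):
        fano = params.sigma1 ** 2 + (params.sigma1 ** 2 - 1) * beta * nbar / f
    fano = np.where(f > 0, fano, 1.0)
    fano = np.maximum(fano, 1.0)
    m = 0.5 * ((fano - 1) + np.sqrt((fano - 1) ** 2 + 4))
    return m - 1.0


def generate_visit_log(profile: WeeklyArrivalProfile, params: ModelParams,
                       n_weeks: int, seed=None,
                       period_start: pd.Timestamp = DEFAULT_EPOCH) -> VisitLog:
    """Simulate an agent-level visit log over `n_weeks` weeks.

    Arrivals follow a (compound) Poisson process with hourly intensity
    f(t); each patient exits with hazard beta(t) * max(1 + eps_k, 0), where
    eps_k ~ N(0, sigma2) is an hourly multiplier shared by all present
    patients.  Timestamps are rounded to minute resolution (departures at
    least one minute after arrival).  Reproducible given `seed`.
    """
    if n_weeks < 1:
        raise ValueError("need at least one week")
    rng = np.random.default_rng(seed)

    n_hours = n_weeks * WEEK_HOURS
    buffer_hours = 240  # lets every stay run to completion (~e^-60 tail)
    total_hours = n_hours + buffer_hours

    week_idx = np.arange(total_hours) % WEEK_HOURS
    flux = profile.hourly_flux[week_idx]
    beta = params.beta_hourly()[week_idx]
    lam_b = _batch_rate(profile, params)[week_idx]

    # systematic noise: hourly exit-rate multiplier shared by all patients.
    # The mean shift beta*sigma2^2/2 removes the Jensen bias of a multiplier
    # held constant over an hour (E[exp(-beta(1+eps)dt)] > exp(-beta*dt)),
    # matching the Ito convention of the Langevin model.
    eps = rng.standard_normal(total_hours) * params.sigma2
    ito_shift = 0.5 * beta * params.sigma2 ** 2
    hazard = beta * np.maximum(1.0 + eps + ito_shift, 0.0)

    # arrivals: events per hour, then batch sizes per event
    mean_batch = 1.0 + lam_b
    ev_counts = rng.poisson(flux[:n_hours] / mean_batch[:n_hours])
    ev_hour = np.repeat(np.arange(n_hours), ev_counts)
    ev_minute = rng.integers(0, 60, size=ev_hour.size)
    batch = 1 + rng.poisson(lam_b[ev_hour])
    arr_minutes = np.repeat(ev_hour * 60 + ev_minute, batch)
    arrivals = arr_minutes / 60.0

    # exits: invert the cumulative hazard at a unit-exponential deviate
    cumhaz = np.concatenate([[0.0], np.cumsum(hazard)])
    ha = (arr_minutes // 60).astype(np.int64)
    lam_a = cumhaz[ha] + (arrivals - ha) * hazard[ha]
    target = lam_a + rng.exponential(size=arrivals.size)
    truncated = int(np.sum(target >= cumhaz[-1]))
    target = np.minimum(target, cumhaz[-1] - 1e-9)
    j = np.clip(np.searchsorted(cumhaz, target, side="right") - 1,
                0, total_hours - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (target - cumhaz[j]) / hazard[j]
    departures = j + np.where(hazard[j] > 0, frac, 0.0)
    dep_minutes = np.maximum(np.rint(departures * 60), arr_minutes + 1)

    order = np.argsort(arr_minutes, kind="stable")
    meta = {
        "seed": None if seed is None else int(seed),
        "n_weeks": int(n_weeks),
        "sigma1": params.sigma1,
        "sigma2": params.sigma2,
        "beta_by_daygroup": dict(params.beta_by_daygroup),
        "truncated_stays": truncated,
    }
    return VisitLog(arrivals_h=arr_minutes[order] / 60.0,
                    departures_h=dep_minutes[order] / 60.0,
                    period_start=period_start, n_weeks=n_weeks,
                    metadata=meta)


def write_visit_log(log: VisitLog, path) -> None:
    """CSV with header visit_id, arrival_ts, departure_ts (ISO-8601, minute
    precision) plus a YAML metadata sidecar `<path>.meta.yaml`."""
    path = Path(path)
    frame = log.to_frame()
    frame["arrival_ts"] = frame["arrival_ts"].dt.strftime("%Y-%m-%dT%H:%M")
    frame["departure_ts"] = frame["departure_ts"].dt.strftime("%Y-%m-%dT%H:%M")
    frame.to_csv(path, index=False)
    sidecar = {"period_start": str(log.period_start),
               "n_weeks": int(log.n_weeks),
               "metadata": log.metadata}
    with open(str(path) + ".meta.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)


def read_visit_log(path) -> VisitLog:
    """Read a visit-log CSV (with optional metadata sidecar)."""
    path = Path(path)
    frame = pd.read_csv(path, parse_dates=["arrival_ts", "departure_ts"])
    sidecar_path = Path(str(path) + ".meta.yaml")
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            sidecar = yaml.safe_load(fh)
        period_start = pd.Timestamp(sidecar["period_start"])
        n_weeks = int(sidecar["n_weeks"])
        metadata = sidecar.get("metadata", {})
    else:
        first = frame["arrival_ts"].min()
        # snap back to the preceding Sunday 07:00 week epoch
        anchor = first.normalize() + pd.Timedelta(hours=7)
        if anchor > first:
            anchor -= pd.Timedelta(days=1)
        anchor -= pd.Timedelta(days=(anchor.dayofweek + 1) % 7)
        period_start = anchor
        span_h = (frame["arrival_ts"].max() - period_start).total_seconds() / 3600
        n_weeks = int(np.ceil((span_h + 1e-9) / WEEK_HOURS)) or 1
        metadata = {}
    arrivals = (frame["arrival_ts"] - period_start).dt.total_seconds() / 3600
    departures = (frame["departure_ts"] - period_start).dt.total_seconds() / 3600
    return VisitLog(arrivals_h=arrivals.to_numpy(),
                    departures_h=departures.to_numpy(),
                    period_start=period_start, n_weeks=n_weeks,
                    metadata=metadata)
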