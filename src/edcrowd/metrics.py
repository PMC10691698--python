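"""Crowding metrics computed from visit logs (empirical or synthetic).

Four metrics drive the modelling pipeline: the hourly arrival flux f(t), the
hourly exit flux, the momentary occupancy n(t), and the "patient hours"
C = integral of n(t) over a shift window -- accumulated presence, the
quantity that summarizes how loaded a shift was.  Relative crowding
x = C_shift / <C> normalizes a shift's patient hours by the long-run mean of
the same weekly shift.

Conventions: a patient is present on [arrival, departure) (half-open, so
nobody is double-counted at a boundary); arrivals and exits bin by their own
timestamp into half-open hourly bins [h, h+1); all times are fractional hours
since the log's week epoch (Sunday 07:00).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .model import OccupancySeries
from .params import DAY_NAMES, SHIFT_HOURS, SHIFT_NAMES, WEEK_HOURS
from .synth import VisitLog

__all__ = [
    "HourlyStats", "ShiftSummary",
    "occupancy_from_log", "hourly_flux", "hourly_occupancy",
    "patient_hours", "patient_hours_from_log", "shift_summaries",
    "relative_crowding", "survival_curve", "kl_divergence", "r_squared",
    "TOP10_SHIFT_KEYS",
]

#: the 10 most crowded weekly shifts: Sunday-Thursday morning and afternoon
TOP10_SHIFT_KEYS = tuple((day, shift) for day in DAY_NAMES[:5]
                         for shift in ("morning", "afternoon"))


@dataclass(frozen=True)
class HourlyStats:
    """Per-weekly-hour mean and STD across weeks."""

    weekly_hour: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    n_obs: int

    def __post_init__(self) -> None:
        if self.n_obs < 1:
            raise ValueError("need at least one week of observations")
        if np.any(np.asarray(self.std) < 0):
            raise ValueError("negative STD")


@dataclass(frozen=True)
class ShiftSummary:
    """Patient hours of one shift occurrence.

    ``shift_key`` identifies the weekly shift (day name, shift name); the
    ``relative`` crowding x = C / <C over all occurrences of the same key>
    is filled by :func:`relative_crowding`.
    """

    shift_key: tuple[str, str]
    window: tuple[float, float]
    patient_hours: float
    week: int
    relative: float | None = None


def _require_valid_grid(log: VisitLog, t: np.ndarray) -> None:
    if t.size == 0:
        raise ValueError("empty time grid")
    if t.min() < 0 or t.max() > log.period_hours:
        raise ValueError("time grid extends outside the log period")


def occupancy_from_log(log: VisitLog, t_grid: Sequence[float]) -> OccupancySeries:
    """Momentary occupancy n(t) = #{visits with arrival <= t < departure}."""
    t = np.asarray(t_grid, dtype=float)
    _require_valid_grid(log, t)
    arr = log.arrivals_h  # already sorted
    dep = np.sort(log.departures_h)
    n_in = np.searchsorted(arr, t, side="right")
    n_out = np.searchsorted(dep, t, side="right")
    return OccupancySeries(t, (n_in - n_out).astype(float))


def _per_week_stats(per_hour: np.ndarray, n_weeks: int,
                    skip_weeks: int) -> HourlyStats:
    weekly = per_hour.reshape(n_weeks, WEEK_HOURS)[skip_weeks:]
    if weekly.shape[0] < 1:
        raise ValueError("no weeks left after skipping warm-up")
    return HourlyStats(weekly_hour=np.arange(WEEK_HOURS),
                       mean=weekly.mean(axis=0),
                       std=weekly.std(axis=0),
                       n_obs=weekly.shape[0])


def hourly_flux(log: VisitLog, kind: str = "arrival",
                skip_weeks: int = 0) -> tuple[np.ndarray, HourlyStats]:
    """Hourly arrival (or exit) counts plus per-weekly-hour stats.

    Returns the full per-hour count vector (n_weeks * 168 bins) and the
    mean/STD of each weekly hour across weeks.  Exit counts only include
    departures inside the log period.  ``skip_weeks`` drops leading warm-up
    weeks from the cross-week statistics (the log starts from an empty ED).
    """
    if kind not in ("arrival", "exit"):
        raise ValueError("kind must be 'arrival' or 'exit'")
    times = log.arrivals_h if kind == "arrival" else log.departures_h
    n_bins = int(log.period_hours)
    counts = np.bincount(np.floor(times[times < n_bins]).astype(int),
                         minlength=n_bins).astype(float)
    return counts, _per_week_stats(counts, log.n_weeks, skip_weeks)


def hourly_occupancy(log: VisitLog, skip_weeks: int = 0
                     ) -> tuple[OccupancySeries, HourlyStats]:
    """Occupancy sampled on the hour, plus per-weekly-hour stats across weeks."""
    t = np.arange(int(log.period_hours), dtype=float)
    series = occupancy_from_log(log, t)
    return series, _per_week_stats(series.counts, log.n_weeks, skip_weeks)


def patient_hours(occupancy: OccupancySeries,
                  window: tuple[float, float]) -> float:
    """Patient hours C = integral of n(t) over [T, T+dT), by the trapezoid
    rule on the sampled series (endpoints interpolated linearly)."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive length")
    if t0 < occupancy.times[0] or t1 > occupancy.times[-1]:
        raise ValueError("window extends outside the occupancy series")
    inside = occupancy.times[(occupancy.times > t0) & (occupancy.times < t1)]
    grid = np.concatenate([[t0], inside, [t1]])
    vals = np.interp(grid, occupancy.times, occupancy.counts)
    return float(np.trapezoid(vals, grid))


def patient_hours_from_log(log: VisitLog, window: tuple[float, float]) -> float:
    """Exact patient hours over a window: the summed in-window stay duration
    of every visit (the occupancy step function integrated exactly)."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive length")
    overlap = (np.minimum(log.departures_h, t1)
               - np.maximum(log.arrivals_h, t0))
    return float(np.sum(np.maximum(overlap, 0.0)))


def shift_summaries(log: VisitLog, skip_weeks: int = 0) -> list[ShiftSummary]:
    """Patient hours for every 8-hour shift occurrence in the log (exact
    integration of the visit intervals)."""
    out: list[ShiftSummary] = []
    for week in range(skip_weeks, log.n_weeks):
        for day in range(7):
            for s, shift_name in enumerate(SHIFT_NAMES):
                t0 = week * WEEK_HOURS + day * 24 + s * SHIFT_HOURS
                window = (float(t0), float(t0 + SHIFT_HOURS))
                c = patient_hours_from_log(log, window)
                out.append(ShiftSummary(shift_key=(DAY_NAMES[day], shift_name),
                                        window=window, patient_hours=c,
                                        week=week))
    return out


def relative_crowding(summaries: Sequence[ShiftSummary]) -> list[ShiftSummary]:
    """Fill x = C / <C> where <C> is the mean patient hours over all
    occurrences of the same weekly shift."""
    if not summaries:
        raise ValueError("no shift summaries")
    means: dict[tuple[str, str], float] = {}
    for key in {s.shift_key for s in summaries}:
        values = [s.patient_hours for s in summaries if s.shift_key == key]
        means[key] = float(np.mean(values))
        if means[key] == 0:
            raise ZeroDivisionError(f"mean patient hours is zero for {key}")
    return [replace(s, relative=s.patient_hours / means[s.shift_key])
            for s in summaries]


def survival_curve(log: VisitLog, cohort_start: float | None = None,
                   pool_weeks: bool = True, max_hours: float = 48.0,
                   tail_cutoff: float = 0.05
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    """Remaining fraction of an arrival cohort versus time since arrival,
    with the exit rate beta fitted by least squares on the log fraction.

    The cohort is every patient arriving during the hour starting at
    ``cohort_start`` (a weekly hour if ``pool_weeks``, pooling the same hour
    of every week); ``cohort_start=None`` pools all patients.  The fit uses
    the span where the remaining fraction is at least ``tail_cutoff``.

    Returns ``(times_since_arrival, fractions, beta_fit)``; ``beta_fit`` is
    NaN when the cohort empties before a decay rate can be fitted.
    """
    if cohort_start is None:
        mask = np.ones(len(log), dtype=bool)
    elif pool_weeks:
        wh = log.arrivals_h % WEEK_HOURS
        h0 = cohort_start % WEEK_HOURS
        mask = (wh >= h0) & (wh < h0 + 1)
    else:
        mask = (log.arrivals_h >= cohort_start) & (log.arrivals_h < cohort_start + 1)
    durations = (log.departures_h - log.arrivals_h)[mask]
    if durations.size == 0:
        raise ValueError("empty cohort")

    times = np.arange(0, max_hours + 1e-9, 0.25)
    fractions = np.array([(durations > t).mean() for t in times])
    keep = fractions >= max(tail_cutoff, 1.0 / durations.size)
    if keep.sum() < 3:
        return times, fractions, float("nan")
    slope = np.polyfit(times[keep], np.log(fractions[keep]), 1)[0]
    return times, fractions, float(-slope)


def _align_histograms(p, q) -> tuple[np.ndarray, np.ndarray]:
    """Bring two histograms onto their union support.

    Each histogram is either a weight vector (shared support assumed) or a
    ``(support, weights)`` pair; weights may be counts or probabilities.
    """
    if isinstance(p, tuple) and isinstance(q, tuple):
        sp, wp = np.asarray(p[0]), np.asarray(p[1], dtype=float)
        sq, wq = np.asarray(q[0]), np.asarray(q[1], dtype=float)
        support = np.union1d(sp, sq)
        ap = np.zeros(support.size)
        aq = np.zeros(support.size)
        ap[np.searchsorted(support, sp)] = wp
        aq[np.searchsorted(support, sq)] = wq
        return ap, aq
    ap = np.asarray(p, dtype=float)
    aq = np.asarray(q, dtype=float)
    if ap.shape != aq.shape:
        raise ValueError("histograms on a shared support must match in length")
    return ap, aq


def kl_divergence(p, q, pseudocount: float = 0.0) -> float:
    """Kullback-Leibler divergence KL(p || q) in nats.

    ``p`` and ``q`` are weight vectors on a shared support or
    ``(support, weights)`` pairs (weights may be unnormalized counts).
    ``pseudocount`` is added to every bin of both histograms on the union
    support before normalizing -- use 0.5 (add-one-half) when comparing raw
    count histograms whose supports may not overlap exactly.
    """
    ap, aq = _align_histograms(p, q)
    ap = ap + pseudocount
    aq = aq + pseudocount
    if ap.sum() <= 0 or aq.sum() <= 0:
        raise ValueError("histograms must have positive total weight")
    ap = ap / ap.sum()
    aq = aq / aq.sum()
    if np.any((aq == 0) & (ap > 0)):
        raise ZeroDivisionError(
            "q has empty bins where p has mass; pass a pseudocount")
    mask = ap > 0
    return float(np.sum(ap[mask] * np.log(ap[mask] / aq[mask])))


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("series must have matching shapes")
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("observed series is constant; R^2 undefined")
    return float(1.0 - np.sum((obs - pred) ** 2) / ss_tot)
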