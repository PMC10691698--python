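"""Forward models of ED occupancy.

Three views of the same birth-death population process, in increasing order
of fidelity to the data:

* the mean-field ODE  dn/dt = f(t) - beta(t) n  and its closed-form solution
  (exact for piecewise-constant f and beta);
* the exact stochastic birth-death process (event-driven simulation of the
  master equation), which carries demographic noise only;
* the Langevin diffusion approximation
      dn = [f - beta (1 + xi2) n] dt + sqrt(f + beta n) dW1,
  where xi1 (demographic) and xi2 (systematic) are independent white noises
  of magnitude sigma1 and sigma2.  This is the workhorse for ensembles.

The Langevin equation is integrated in the Ito sense with Euler-Maruyama;
noise increments are Gaussian with standard deviation sigma_i * sqrt(dt).
The square-root argument is clamped at zero and any post-step negative
occupancy is reflected to its absolute value, which preserves non-negativity
with negligible bias at the typical occupancy of ~55 patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .params import ModelParams, WeeklyArrivalProfile, WEEK_HOURS

__all__ = [
    "OccupancySeries", "EnsembleStats",
    "mean_field_fixed_point", "mean_field_trajectory", "mean_field_weekly",
    "simulate_exact", "simulate_langevin", "langevin_hourly_matrix",
    "ensemble_stats",
]


@dataclass(frozen=True)
class OccupancySeries:
    """Momentary patient count n(t) on a time grid (hours since week epoch).

    Counts are real-valued for Langevin output and integer-valued for the
    exact simulator or counts reconstructed from a visit log.
    """

    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if times.ndim != 1 or times.size == 0:
            raise ValueError("time grid must be a non-empty 1-D array")
        if counts.shape != times.shape:
            raise ValueError("times and counts must have matching shapes")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(counts < -1e-12):
            raise ValueError("occupancy counts must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class EnsembleStats:
    """Hour-by-hour ensemble statistics over occupancy realizations."""

    times: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    #: pooled occupancy histogram: (integer support, probabilities)
    histogram: tuple[np.ndarray, np.ndarray]


def mean_field_fixed_point(f_bar: float, beta_bar: float) -> float:
    """Stationary mean occupancy n* = f/beta for constant rates."""
    if beta_bar <= 0:
        raise ValueError("mean exit rate beta must be positive")
    if f_bar < 0:
        raise ValueError("mean arrival flux must be non-negative")
    return f_bar / beta_bar


def _hourly_rates(profile: WeeklyArrivalProfile, params: ModelParams,
                  hours: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(f, beta) for each integer hour since week epoch (periodic)."""
    idx = np.floor(hours).astype(int) % WEEK_HOURS
    return profile.hourly_flux[idx], params.beta_hourly()[idx]


def mean_field_trajectory(profile: WeeklyArrivalProfile, params: ModelParams,
                          n0: float, t_grid: Sequence[float]) -> OccupancySeries:
    """Deterministic mean occupancy nbar(t), starting from n0 at t_grid[0].

    With f and beta piecewise constant over hourly bins the ODE solution is
    exact: within each hour nbar relaxes exponentially toward f/beta, and
    hours are chained analytically, so there is no integration error.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    if n0 < 0:
        raise ValueError("initial occupancy must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")

    t0 = t[0]
    # occupancy at hour boundaries t0, ceil(t0), ceil(t0)+1, ... up to t[-1]
    boundaries = np.concatenate([[t0], np.arange(np.floor(t0) + 1, np.floor(t[-1]) + 1)])
    n_bound = np.empty(boundaries.size)
    n_bound[0] = n0
    f_b, beta_b = _hourly_rates(profile, params, boundaries)
    for k in range(boundaries.size - 1):
        dt_k = boundaries[k + 1] - boundaries[k]
        decay = np.exp(-beta_b[k] * dt_k)
        n_bound[k + 1] = n_bound[k] * decay + (f_b[k] / beta_b[k]) * (1 - decay)

    # evaluate each requested point from the boundary that starts its hour
    idx = np.searchsorted(boundaries, t, side="right") - 1
    tau = t - boundaries[idx]
    f_t, beta_t = f_b[idx], beta_b[idx]
    decay = np.exp(-beta_t * tau)
    counts = n_bound[idx] * decay + (f_t / beta_t) * (1 - decay)
    return OccupancySeries(t, counts)


def mean_field_weekly(profile: WeeklyArrivalProfile,
                      params: ModelParams) -> OccupancySeries:
    """Periodic steady-state mean occupancy at the 168 hourly marks.

    One burn-in week from the day-averaged fixed point is ample: initial
    conditions decay by e^{-beta * 168} ~ e^{-42} over a week.
    """
    n_start = mean_field_fixed_point(profile.mean, params.mean_beta())
    grid = np.arange(-WEEK_HOURS, WEEK_HOURS, dtype=float)
    traj = mean_field_trajectory(profile, params, n_start, grid)
    return OccupancySeries(np.arange(WEEK_HOURS, dtype=float),
                           traj.counts[WEEK_HOURS:])


def simulate_exact(profile: WeeklyArrivalProfile, params: ModelParams,
                   n0: int, horizon: float, seed=None,
                   t_start: float = 0.0,
                   record: str = "hourly") -> OccupancySeries:
    """Event-driven exact simulation of the birth-death master equation.

    Births occur at rate f(t), each of the n present patients dies (exits)
    at rate beta(t); rates are piecewise constant per hour, so within each
    hour waiting times are exponential and at hour boundaries the memoryless
    clock is simply redrawn.  Systematic noise is not represented here
    (sigma2 must be 0); this simulator is the brute-force oracle for the
    demographic-noise-only model.

    With ``record="hourly"`` returns the integer occupancy sampled at hourly
    marks; with ``record="events"`` returns the full jump chain (the state
    after every birth/death event, prepended with the initial state).
    """
    if record not in ("hourly", "events"):
        raise ValueError("record must be 'hourly' or 'events'")
    if int(n0) != n0 or n0 < 0:
        raise ValueError("n0 must be a non-negative integer")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if params.sigma2 != 0:
        raise ValueError("exact birth-death simulation carries demographic "
                         "noise only; sigma2 must be 0")
    rng = np.random.default_rng(seed)

    n_hours = int(np.floor(horizon))
    sample_times = t_start + np.arange(n_hours + 1, dtype=float)
    samples = np.empty(n_hours + 1, dtype=float)
    samples[0] = n0

    flux_week = profile.hourly_flux
    beta_week = params.beta_hourly()

    # batched uniforms: the python event loop dominates, but rng call
    # overhead per event is still worth avoiding (small first batch keeps
    # short runs cheap)
    buf = rng.random(4096)
    pos = 0

    def next_u() -> float:
        nonlocal buf, pos
        if pos >= buf.size:
            buf = rng.random(65536)
            pos = 0
        u = buf[pos]
        pos += 1
        return u

    n = int(n0)
    t = t_start
    ev_times: list[float] = []
    ev_counts: list[int] = []
    for h in range(n_hours):
        hour_end = t_start + h + 1
        wh = int(np.floor(t_start + h)) % WEEK_HOURS
        f = flux_week[wh]
        beta = beta_week[wh]
        while True:
            rate = f + beta * n
            if rate <= 0:
                break
            wait = -np.log(next_u()) / rate
            if t + wait >= hour_end:
                break
            t += wait
            if next_u() * rate < f:
                n += 1
            else:
                n -= 1
            if record == "events":
                ev_times.append(t)
                ev_counts.append(n)
        t = hour_end
        samples[h + 1] = n
    if record == "events":
        return OccupancySeries(np.concatenate([[t_start], ev_times]),
                               np.concatenate([[n0], ev_counts]))
    return OccupancySeries(sample_times, samples)


def langevin_hourly_matrix(profile: WeeklyArrivalProfile, params: ModelParams,
                           n0: float, horizon: float, dt: float,
                           n_realizations: int, rng: np.random.Generator,
                           t_start: float = 0.0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama integration of the Langevin equation, vectorized over
    realizations, sampled at hourly marks.

    Returns ``(times, counts)`` with counts of shape
    ``(n_realizations, n_hours + 1)`` including the initial state.  dt is
    snapped to an integer number of steps per hour.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_realizations < 1:
        raise ValueError("need at least one realization")
    if n0 < 0:
        raise ValueError("initial occupancy must be non-negative")

    steps_per_hour = max(1, int(round(1.0 / dt)))
    dt_eff = 1.0 / steps_per_hour
    sqrt_dt = np.sqrt(dt_eff)
    n_hours = int(np.floor(horizon))

    flux_week = profile.hourly_flux
    beta_week = params.beta_hourly()
    s1, s2 = params.sigma1, params.sigma2

    n = np.full(n_realizations, float(n0))
    times = t_start + np.arange(n_hours + 1, dtype=float)
    out = np.empty((n_realizations, n_hours + 1))
    out[:, 0] = n

    # noise increments are drawn in float32 (the integrator state stays
    # float64): at sigma*sqrt(dt) ~ 0.1 the quantization is ~1e-8 patients
    # per step, far below the Monte-Carlo resolution, and generation is
    # twice as fast
    noisy = s1 > 0 or s2 > 0
    for h in range(n_hours):
        wh = int(np.floor(t_start + h)) % WEEK_HOURS
        f = flux_week[wh]
        beta = beta_week[wh]
        if noisy:
            dw = rng.standard_normal((2, steps_per_hour, n_realizations),
                                     dtype=np.float32)
            dw1 = dw[0] * np.float32(s1 * sqrt_dt)
            dw2 = dw[1] * np.float32(s2 * sqrt_dt)
        for k in range(steps_per_hour):
            bn = beta * n
            n = n + (f - bn) * dt_eff
            if noisy:
                n += np.sqrt(np.maximum(f + bn, 0.0)) * dw1[k]
                n -= bn * dw2[k]
                np.abs(n, out=n)  # reflect at the n=0 boundary
        out[:, h + 1] = n
    return times, out


def simulate_langevin(profile: WeeklyArrivalProfile, params: ModelParams,
                      n0: float, horizon: float, dt: float = 0.01,
                      n_realizations: int = 1, seed=None,
                      t_start: float = 0.0) -> list[OccupancySeries]:
    """Stochastic occupancy trajectories under both noise channels.

    Thin wrapper over :func:`langevin_hourly_matrix` returning one
    :class:`OccupancySeries` per realization (hourly sampling).  Identical
    seeds and settings give bit-identical trajectories.
    """
    rng = np.random.default_rng(seed)
    times, counts = langevin_hourly_matrix(profile, params, n0, horizon, dt,
                                           n_realizations, rng, t_start)
    return [OccupancySeries(times, counts[i]) for i in range(n_realizations)]


def pooled_histogram(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy histogram on integer support (Langevin samples are rounded
    to the nearest patient count, clipped at zero); probabilities sum to 1."""
    ints = np.maximum(np.rint(np.asarray(samples, dtype=float)), 0).astype(int)
    support, counts = np.unique(ints.ravel(), return_counts=True)
    return support, counts / counts.sum()


def ensemble_stats(realizations: Sequence[OccupancySeries],
                   sample_times: Sequence[float] | None = None) -> EnsembleStats:
    """Hourly ensemble mean, STD and pooled occupancy histogram.

    All realizations must share a grid, or ``sample_times`` must be given,
    in which case each trajectory is sampled onto it by previous-value
    (step) interpolation.  STD is the population STD across realizations.
    """
    if len(realizations) == 0:
        raise ValueError("empty ensemble")
    if sample_times is None:
        times = realizations[0].times
        for r in realizations[1:]:
            if r.times.shape != times.shape or not np.allclose(r.times, times):
                raise ValueError("realizations on different grids; "
                                 "pass sample_times to resample")
        counts = np.stack([r.counts for r in realizations])
    else:
        times = np.asarray(sample_times, dtype=float)
        counts = np.stack([
            r.counts[np.clip(np.searchsorted(r.times, times, side="right") - 1,
                             0, r.times.size - 1)]
            for r in realizations
        ])
    return EnsembleStats(times=times,
                         mean=counts.mean(axis=0),
                         std=counts.std(axis=0),
                         histogram=pooled_histogram(counts))
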