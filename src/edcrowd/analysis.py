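"""Overcrowding statistics and parameter-elasticity scans.

Overcrowding is graded by occupancy thresholds mapped from the top two
NEDOCS levels: ~120 patients marks the onset of severe overcrowding and
~140 dangerous overcrowding.  Tail probabilities P(n > n_s) pool hourly
occupancy samples across the whole week (an optional shift filter restricts
them); the complementary *relative* view looks at a shift's patient hours
relative to its long-run mean, x = C_shift / <C>.

Elasticity scans answer "what-if" questions: how does the overcrowding
probability respond to a uniform change in the arrival flux, a change of so
many minutes in the typical length of stay 1/beta (applied to all day
groups), or a proportional change in the systematic noise sigma2?  All
deltas share common random numbers with the baseline so the reported ratios
are far less noisy than the individual tail estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .metrics import TOP10_SHIFT_KEYS, ShiftSummary, relative_crowding
from .model import langevin_hourly_matrix, mean_field_weekly
from .params import (SHIFT_HOURS, WEEK_HOURS, ModelParams,
                     WeeklyArrivalProfile, shift_of_hour)

__all__ = [
    "SEVERE_THRESHOLD", "DANGEROUS_THRESHOLD",
    "PrecisionError", "OvercrowdingReport", "ElasticityCurve",
    "weekly_hourly_samples", "tail_probability",
    "patient_hours_distribution", "elasticity_scan", "overcrowding_report",
]

SEVERE_THRESHOLD = 120     # patients: onset of severe overcrowding
DANGEROUS_THRESHOLD = 140  # patients: dangerous overcrowding


class PrecisionError(ValueError):
    """Too few samples for a meaningful tail estimate."""


@dataclass
class ElasticityCurve:
    """Tail-probability ratios versus a parameter change."""

    knob: str                   # arrival_flux | length_of_stay | sigma2
    deltas: np.ndarray          # fractional change, or minutes for LOS
    ratio: np.ndarray           # P(n>n_s | delta) / P(n>n_s | 0)
    probs: np.ndarray           # raw tail probabilities
    ratio_se: np.ndarray        # propagated binomial standard errors
    threshold: float


@dataclass
class OvercrowdingReport:
    """Tail probabilities at the severe/dangerous thresholds plus the
    relative-crowding tails P(x > 1 + delta) over the top-10 shifts."""

    thresholds: dict[str, float]
    tail_probs: dict[str, tuple[float, float]]       # (probability, SE)
    relative_tails: dict[float, tuple[float, float]]  # delta -> (prob, SE)


def weekly_hourly_samples(profile: WeeklyArrivalProfile, params: ModelParams,
                          n_realizations: int = 10_000, seed=0,
                          dt: float = 0.01, burn_in: int = 48) -> np.ndarray:
    """Hourly occupancy samples of a simulated week after burn-in.

    Returns shape ``(n_realizations, 168)``: column h is the occupancy
    recorded on the hour at weekly hour h.  A fresh generator is built from
    ``seed``, so calls with identical settings share random numbers.
    """
    rng = np.random.default_rng(seed)
    n0 = mean_field_weekly(profile, params).counts[-burn_in % WEEK_HOURS]
    _, counts = langevin_hourly_matrix(profile, params, n0,
                                       horizon=burn_in + WEEK_HOURS, dt=dt,
                                       n_realizations=n_realizations, rng=rng,
                                       t_start=float(-burn_in))
    return counts[:, burn_in:burn_in + WEEK_HOURS]


def tail_probability(samples: np.ndarray, threshold: float,
                     shift_filter: str | None = None,
                     min_samples: int = 1000) -> tuple[float, float]:
    """Fraction of hourly samples strictly exceeding ``threshold``, with the
    binomial standard error.

    ``samples`` is either a flat array of pooled hourly occupancies or a
    ``(realizations, 168)`` weekly matrix; a ``shift_filter`` ('morning',
    'afternoon' or 'night') restricts the pooled hours and requires the
    weekly matrix form.
    """
    x = np.asarray(samples, dtype=float)
    if shift_filter is not None:
        if x.ndim != 2 or x.shape[1] != WEEK_HOURS:
            raise ValueError("shift filtering needs (realizations, 168) samples")
        mask = shift_of_hour(np.arange(WEEK_HOURS)) == shift_filter
        if not mask.any():
            raise ValueError(f"unknown shift {shift_filter!r}")
        x = x[:, mask]
    x = x.ravel()
    if x.size < min_samples:
        raise PrecisionError(
            f"{x.size} samples is too few for a tail estimate")
    p = float(np.mean(x > threshold))
    se = float(np.sqrt(p * (1 - p) / x.size))
    return p, se


def patient_hours_distribution(summaries: Sequence[ShiftSummary],
                               top10_filter: bool = True,
                               bins: int | Sequence[float] = 30
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distribution of relative crowding x = C_shift / <C>.

    Returns ``(bin_edges, density, x_values)``; the density integrates to 1.
    With ``top10_filter`` only the 10 most crowded weekly shifts
    (Sunday-Thursday morning and afternoon) are pooled.
    """
    if not summaries:
        raise ValueError("no shift summaries")
    if any(s.relative is None for s in summaries):
        summaries = relative_crowding(summaries)
    keys = set(TOP10_SHIFT_KEYS)
    x = np.array([s.relative for s in summaries
                  if not top10_filter or s.shift_key in keys])
    density, edges = np.histogram(x, bins=bins, density=True)
    return edges, density, x


def _apply_knob(params: ModelParams, profile: WeeklyArrivalProfile,
                knob: str, delta: float
                ) -> tuple[ModelParams, WeeklyArrivalProfile]:
    if knob == "arrival_flux":
        return params, profile.scaled(1.0 + delta)
    if knob == "length_of_stay":
        # delta is minutes added to the typical stay 1/beta, all day groups
        new_betas = {g: 1.0 / (1.0 / b + delta / 60.0)
                     for g, b in params.beta_by_daygroup.items()}
        if any(1.0 / b + delta / 60.0 <= 0 for b in
               params.beta_by_daygroup.values()):
            raise ValueError("length-of-stay change makes a stay non-positive")
        return params.replace(beta_by_daygroup=new_betas), profile
    if knob == "sigma2":
        return params.replace(sigma2=params.sigma2 * (1.0 + delta)), profile
    raise ValueError(f"unknown knob {knob!r}")


def elasticity_scan(params: ModelParams, profile: WeeklyArrivalProfile,
                    knob: str, deltas: Sequence[float],
                    threshold: float = SEVERE_THRESHOLD,
                    n_realizations: int = 10_000, seed=0,
                    dt: float = 0.01) -> ElasticityCurve:
    """Ratio of overcrowding tail probabilities versus a parameter change.

    ``deltas`` must include 0 (the baseline).  Common random numbers are
    used across deltas, so ratios are estimated with strongly correlated
    noise; the quoted ratio SE conservatively propagates the independent
    binomial errors.
    """
    deltas = np.asarray(list(deltas), dtype=float)
    if not np.isclose(deltas, 0.0).any():
        raise ValueError("deltas must include the baseline 0")

    probs = np.empty(deltas.size)
    ses = np.empty(deltas.size)
    for i, d in enumerate(deltas):
        p_i, prof_i = _apply_knob(params, profile, knob, float(d))
        samples = weekly_hourly_samples(prof_i, p_i, n_realizations, seed, dt)
        probs[i], ses[i] = tail_probability(samples, threshold)

    base = probs[np.isclose(deltas, 0.0)][0]
    base_se = ses[np.isclose(deltas, 0.0)][0]
    if base == 0:
        raise ZeroDivisionError(
            "baseline tail probability is 0 in the sample; "
            "increase n_realizations")
    ratio = probs / base
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.sqrt((ses / np.where(probs > 0, probs, np.inf)) ** 2
                      + (base_se / base) ** 2)
    return ElasticityCurve(knob=knob, deltas=deltas, ratio=ratio, probs=probs,
                           ratio_se=ratio * rel, threshold=threshold)


def _shift_patient_hours_matrix(samples: np.ndarray) -> np.ndarray:
    """Per-realization patient hours for each of the 21 weekly shifts,
    trapezoid-integrated over the hourly samples (periodic closure)."""
    closed = np.concatenate([samples, samples[:, :1]], axis=1)  # hour 168 = 0
    hours = np.arange(WEEK_HOURS + 1)
    out = np.empty((samples.shape[0], WEEK_HOURS // SHIFT_HOURS))
    for s in range(out.shape[1]):
        seg = slice(s * SHIFT_HOURS, (s + 1) * SHIFT_HOURS + 1)
        out[:, s] = np.trapezoid(closed[:, seg], hours[seg], axis=1)
    return out


def overcrowding_report(params: ModelParams, profile: WeeklyArrivalProfile,
                        n_realizations: int = 10_000, seed=0,
                        thresholds: dict[str, float] | None = None,
                        deltas: Sequence[float] = (0.2, 0.4),
                        dt: float = 0.01) -> OvercrowdingReport:
    """Model overcrowding report: absolute tails at the severe/dangerous
    thresholds and relative tails P(x > 1 + delta) over the top-10 shifts."""
    thresholds = thresholds or {"severe": SEVERE_THRESHOLD,
                                "dangerous": DANGEROUS_THRESHOLD}
    samples = weekly_hourly_samples(profile, params, n_realizations, seed, dt)
    tails = {name: tail_probability(samples, thr)
             for name, thr in thresholds.items()}

    c = _shift_patient_hours_matrix(samples)
    shift_names = shift_of_hour(np.arange(0, WEEK_HOURS, SHIFT_HOURS))
    top10 = np.array([
        (i // 3 < 5) and shift_names[i] in ("morning", "afternoon")
        for i in range(c.shape[1])
    ])
    x = (c / c.mean(axis=0, keepdims=True))[:, top10].ravel()
    rel_tails = {}
    for d in deltas:
        p = float(np.mean(x > 1.0 + d))
        rel_tails[float(d)] = (p, float(np.sqrt(p * (1 - p) / x.size)))
    return OvercrowdingReport(thresholds=dict(thresholds),
                              tail_probs=tails, relative_tails=rel_tails)
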