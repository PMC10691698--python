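"""Two-stage parameter estimation for the occupancy model.

Stage I (deterministic): the four day-group exit rates beta are fitted by
least squares between the mean-field weekly occupancy (closed-form solution
of the rate ODE with the empirical arrival flux) and the observed hourly
occupancy means.  The fit is simultaneous over all four parameters, since
the solution couples adjacent days through the initial condition.

Stage II (stochastic): with the betas fixed, the noise magnitudes
sigma = (sigma1, sigma2) are estimated by grid search.  At every grid point
an ensemble of simulated weeks yields the model's hour-by-hour STD
S(sigma, t_i); under the assumption that the observed hourly STDs S_i carry
additional white Gaussian observation noise of variance p^2, maximizing the
likelihood is equivalent to minimizing the mean square error
MSE(sigma) = sum_i (S_i - S(sigma, t_i))^2 / n, and the fitted observation
variance is p^2 = MSE(sigma*).

Uncertainty: the 1-D likelihood profile along each sigma axis (the other
coordinate held at the optimum),
    L(sigma_i) = C exp[- (n/2) MSE(sigma_i) / MSE(sigma*)],
is fitted to a Gaussian whose STD is reported as the 1-STD half-width.

The same Gaussian-profile construction provides the beta uncertainties via
the curvature of the stage-I squared-error surface (Gauss-Newton covariance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .metrics import (HourlyStats, hourly_flux, hourly_occupancy, r_squared)
from .model import langevin_hourly_matrix, mean_field_weekly
from .params import DAY_GROUPS, WEEK_HOURS, ModelParams, WeeklyArrivalProfile
from .synth import VisitLog

__all__ = [
    "GridSpec", "LikelihoodSurface", "FitResult", "EstimationError",
    "GridBoundaryError", "fit_betas", "noise_mle", "mle_uncertainty",
    "fit_two_stage",
]


class EstimationError(RuntimeError):
    """Raised when a fit is non-identifiable or degenerate."""


class GridBoundaryError(EstimationError):
    """The MSE argmin landed on the search-grid boundary: enlarge the grid."""


@dataclass(frozen=True)
class GridSpec:
    """Coarse-to-fine search grid over (sigma1, sigma2).

    The coarse pass covers the full rectangle; one refinement pass re-scans
    a window of +-1 coarse step around the argmin at the fine steps.
    """

    sigma1_range: tuple[float, float] = (0.5, 2.0)
    sigma2_range: tuple[float, float] = (0.0, 1.0)
    coarse_step1: float = 0.1
    coarse_step2: float = 0.05
    fine_step1: float = 0.025
    fine_step2: float = 0.02

    def coarse_axes(self) -> tuple[np.ndarray, np.ndarray]:
        a1 = np.arange(self.sigma1_range[0],
                       self.sigma1_range[1] + 1e-9, self.coarse_step1)
        a2 = np.arange(self.sigma2_range[0],
                       self.sigma2_range[1] + 1e-9, self.coarse_step2)
        return a1, a2

    def fine_axes(self, center: tuple[float, float]
                  ) -> tuple[np.ndarray, np.ndarray]:
        lo1 = max(self.sigma1_range[0], center[0] - self.coarse_step1)
        hi1 = min(self.sigma1_range[1], center[0] + self.coarse_step1)
        lo2 = max(self.sigma2_range[0], center[1] - self.coarse_step2)
        hi2 = min(self.sigma2_range[1], center[1] + self.coarse_step2)
        return (np.arange(lo1, hi1 + 1e-9, self.fine_step1),
                np.arange(lo2, hi2 + 1e-9, self.fine_step2))


@dataclass
class LikelihoodSurface:
    """Grid MSE surface for the noise magnitudes."""

    grid: np.ndarray        # (n_points, 2) sigma pairs
    mse: np.ndarray         # (n_points,)
    argmin: tuple[float, float]
    p2: float               # fitted observation-noise variance = MSE(sigma*)
    n_points: int           # number of hourly data points behind the MSE

    def axis_profile(self, axis: int) -> tuple[np.ndarray, np.ndarray]:
        """1-D MSE profile along one sigma axis through the argmin."""
        other = 1 - axis
        on_line = np.isclose(self.grid[:, other], self.argmin[other])
        order = np.argsort(self.grid[on_line, axis])
        return self.grid[on_line, axis][order], self.mse[on_line][order]


@dataclass
class FitResult:
    """Outcome of the two-stage estimation."""

    params: ModelParams
    uncertainties: dict[str, float]
    diagnostics: dict[str, float] = field(default_factory=dict)
    surface: LikelihoodSurface | None = None


def _empirical_flux_profile(log: VisitLog, skip_weeks: int = 1
                            ) -> WeeklyArrivalProfile:
    """Mean arrival counts per weekly hour: the empirical f(t)."""
    _, stats = hourly_flux(log, "arrival", skip_weeks=skip_weeks)
    return WeeklyArrivalProfile(stats.mean)


def fit_betas(hourly_occupancy_means: HourlyStats,
              profile: WeeklyArrivalProfile,
              daygroups: tuple[str, ...] = DAY_GROUPS
              ) -> tuple[dict[str, float], dict[str, float]]:
    """Stage I: day-group exit rates from the mean-field weekly solution.

    Minimizes the squared deviation between the closed-form periodic
    mean-field occupancy (piecewise-constant beta, given arrival profile)
    and the observed hourly occupancy means, simultaneously over all day
    groups.  Returns ``(betas, one_std_half_widths)``.
    """
    target = np.asarray(hourly_occupancy_means.mean, dtype=float)
    if target.shape != (WEEK_HOURS,):
        raise ValueError("hourly means must cover the full week")

    def residuals(betas: np.ndarray) -> np.ndarray:
        params = ModelParams(beta_by_daygroup=dict(zip(daygroups, betas)),
                             sigma1=0.0, sigma2=0.0)
        return mean_field_weekly(profile, params).counts - target

    x0 = np.full(len(daygroups), profile.mean / max(target.mean(), 1e-9))
    fit = least_squares(residuals, x0, bounds=(1e-4, 5.0))
    n, p = target.size, len(daygroups)
    jtj = fit.jac.T @ fit.jac
    if np.linalg.cond(jtj) > 1e10:
        raise EstimationError("beta fit is non-identifiable (flat objective)")
    s2 = 2 * fit.cost / (n - p)  # fit.cost = 0.5 * SSR
    cov = s2 * np.linalg.inv(jtj)
    betas = dict(zip(daygroups, fit.x))
    half_widths = dict(zip(daygroups, np.sqrt(np.diag(cov))))
    return betas, half_widths


def _model_hourly_std(profile: WeeklyArrivalProfile, params: ModelParams,
                      n_realizations: int, seed, dt: float = 0.01,
                      burn_in: int = 48) -> np.ndarray:
    """S(sigma, t): hour-by-hour ensemble STD over simulated weeks.

    A fresh generator is built from ``seed`` on every call, so all grid
    points share common random numbers and the MSE surface is smooth.
    """
    rng = np.random.default_rng(seed)
    n0 = mean_field_weekly(profile, params).counts[-burn_in % WEEK_HOURS]
    _, counts = langevin_hourly_matrix(profile, params, n0,
                                       horizon=burn_in + WEEK_HOURS, dt=dt,
                                       n_realizations=n_realizations, rng=rng,
                                       t_start=float(-burn_in))
    week = counts[:, burn_in:burn_in + WEEK_HOURS]  # weekly hours 0..167
    return week.std(axis=0)


def _scan_sigma_std(profile: WeeklyArrivalProfile, betas: dict[str, float],
                    pairs: np.ndarray, n_realizations: int, seed,
                    dt: float = 0.01, burn_in: int = 48) -> np.ndarray:
    """Hour-by-hour ensemble STD S(sigma, t) for many sigma pairs at once.

    All pairs share one Euler-Maruyama sweep and one stream of Gaussian
    increments (sigma only scales the increments), so the grid search uses
    exact common random numbers and a single vectorized pass.  State is kept
    in float32: at ensemble sizes of 10^3-10^4 the Monte-Carlo error is
    orders of magnitude above the float32 resolution.

    Returns S of shape ``(len(pairs), 168)``.
    """
    rng = np.random.default_rng(seed)
    params0 = ModelParams(beta_by_daygroup=betas, sigma1=0.0, sigma2=0.0)
    steps = max(1, int(round(1.0 / dt)))
    dt_eff = np.float32(1.0 / steps)
    sqrt_dt = np.float32(np.sqrt(1.0 / steps))

    flux = profile.hourly_flux
    beta_week = params0.beta_hourly()
    pairs = np.asarray(pairs, dtype=float)
    sig1 = pairs[:, 0:1].astype(np.float32)  # (P, 1) broadcast columns
    sig2 = pairs[:, 1:2].astype(np.float32)

    n0 = mean_field_weekly(profile, params0).counts[-burn_in % WEEK_HOURS]
    n = np.full((pairs.shape[0], n_realizations), np.float32(n0))
    ssum = np.zeros((pairs.shape[0], WEEK_HOURS))
    ssq = np.zeros((pairs.shape[0], WEEK_HOURS))

    for h in range(burn_in + WEEK_HOURS - 1):
        wh = (h - burn_in) % WEEK_HOURS
        f = np.float32(flux[wh])
        b = np.float32(beta_week[wh])
        z = rng.standard_normal((2, steps, n_realizations), dtype=np.float32)
        z1 = z[0] * sqrt_dt
        z2 = z[1] * sqrt_dt
        for k in range(steps):
            bn = b * n
            n = n + (f - bn) * dt_eff
            n += np.sqrt(np.maximum(f + bn, np.float32(0.0))) * (sig1 * z1[k])
            n -= bn * (sig2 * z2[k])
            np.abs(n, out=n)
        idx = h + 1 - burn_in  # state is now at time idx (weekly hour)
        if 0 <= idx < WEEK_HOURS:
            n64 = n.astype(np.float64)
            ssum[:, idx] = n64.sum(axis=1)
            ssq[:, idx] = (n64 * n64).sum(axis=1)
    mean = ssum / n_realizations
    var = np.maximum(ssq / n_realizations - mean ** 2, 0.0)
    return np.sqrt(var)


def noise_mle(S_data: HourlyStats, betas: dict[str, float],
              profile: WeeklyArrivalProfile,
              grid_spec: GridSpec | None = None,
              n_realizations: int = 2000, seed=0,
              dt: float = 0.01) -> LikelihoodSurface:
    """Stage II: grid maximum likelihood for (sigma1, sigma2).

    Every grid point simulates an ensemble of weeks with common random
    numbers and scores the model hourly STD against the data hourly STD by
    MSE; the maximum-likelihood point is the MSE argmin and
    p^2 = MSE(sigma*).  The coarse pass uses a quarter of the realizations;
    the refinement pass around the coarse argmin uses the full count.

    Raises :class:`GridBoundaryError` if the argmin sits on the boundary of
    the requested rectangle.
    """
    spec = grid_spec or GridSpec()
    s_obs = np.asarray(S_data.std, dtype=float)
    n = s_obs.size

    def scan(axis1: np.ndarray, axis2: np.ndarray,
             n_real: int) -> tuple[np.ndarray, np.ndarray]:
        pts = np.array([(s1, s2) for s1 in axis1 for s2 in axis2])
        model_std = _scan_sigma_std(profile, betas, pts, n_real, seed, dt)
        return pts, np.mean((s_obs - model_std) ** 2, axis=1)

    a1, a2 = spec.coarse_axes()
    grid_c, mse_c = scan(a1, a2, max(n_realizations // 4, 200))
    center = tuple(grid_c[np.argmin(mse_c)])

    f1, f2 = spec.fine_axes(center)
    grid_f, mse_f = scan(f1, f2, n_realizations)
    best = grid_f[np.argmin(mse_f)]

    grid = np.vstack([grid_c, grid_f])
    mse = np.concatenate([mse_c, mse_f])
    argmin = (float(best[0]), float(best[1]))

    on_edge = (np.isclose(argmin[0], spec.sigma1_range).any()
               or np.isclose(argmin[1], spec.sigma2_range).any())
    if on_edge:
        raise GridBoundaryError(
            f"argmin {argmin} lies on the search boundary; enlarge the grid")
    return LikelihoodSurface(grid=grid, mse=mse, argmin=argmin,
                             p2=float(mse.min()), n_points=n)


def mle_uncertainty(surface: LikelihoodSurface,
                    n: int | None = None) -> dict[str, float]:
    """1-STD half-widths of sigma1 and sigma2 from Gaussian fits to the
    per-axis likelihood profiles L(sigma_i) = C exp[-(n/2) MSE_i / MSE*]."""
    n = n if n is not None else surface.n_points
    out: dict[str, float] = {}
    for axis, name in enumerate(("sigma1", "sigma2")):
        x, mse = surface.axis_profile(axis)
        if x.size < 3:
            raise EstimationError(f"too few grid points along {name}")
        loglike = -0.5 * n * (mse / surface.p2 - 1.0)
        if np.ptp(loglike) < 1e-9:
            raise EstimationError(f"flat likelihood profile along {name}")
        # a Gaussian in L is a parabola in log L; fit it on the points that
        # carry likelihood mass (within ~5 sigma of the peak), weighted by L
        keep = loglike > loglike.max() - 12.5
        if keep.sum() < 3:  # fall back to the 3 points bracketing the peak
            i = int(np.argmax(loglike))
            keep = np.zeros_like(keep)
            keep[max(i - 1, 0):i + 2] = True
        if keep.sum() < 3:
            raise EstimationError(f"too few informative points along {name}")
        x0 = x[int(np.argmax(loglike))]  # centre for conditioning
        coeffs = np.polyfit(x[keep] - x0, loglike[keep], 2,
                            w=np.exp(loglike[keep] - loglike.max()))
        if coeffs[0] >= 0:
            raise EstimationError(
                f"profile along {name} is not unimodal at the optimum")
        out[name] = float(1.0 / np.sqrt(-2.0 * coeffs[0]))
    return out


def fit_two_stage(log: VisitLog, grid_spec: GridSpec | None = None,
                  n_realizations: int = 2000, seed: int = 0,
                  dt: float = 0.01, skip_weeks: int = 1,
                  diagnostics: bool = True) -> FitResult:
    """Full pipeline: betas from the mean-field fit, then the sigma grid MLE,
    with Gaussian uncertainties and goodness-of-fit diagnostics."""
    profile = _empirical_flux_profile(log, skip_weeks=skip_weeks)
    _, occ_stats = hourly_occupancy(log, skip_weeks=skip_weeks)

    betas, beta_unc = fit_betas(occ_stats, profile)
    surface = noise_mle(occ_stats, betas, profile, grid_spec,
                        n_realizations=n_realizations, seed=seed, dt=dt)
    sigma_unc = mle_uncertainty(surface)

    params = ModelParams(beta_by_daygroup=betas,
                         sigma1=surface.argmin[0], sigma2=surface.argmin[1])
    uncertainties = {f"beta_{g}": beta_unc[g] for g in betas}
    uncertainties.update(sigma_unc)

    diag: dict[str, float] = {"p2": surface.p2}
    if diagnostics:
        model_mean = mean_field_weekly(profile, params).counts
        diag["r2_occupancy_mean"] = r_squared(occ_stats.mean, model_mean)
        model_std = _model_hourly_std(profile, params, n_realizations, seed, dt)
        diag["r2_occupancy_std"] = r_squared(occ_stats.std, model_std)
    return FitResult(params=params, uncertainties=uncertainties,
                     diagnostics=diag, surface=surface)
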