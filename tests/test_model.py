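import numpy as np
import pytest
from scipy import stats

from edcrowd.metrics import kl_divergence
from edcrowd.model import (OccupancySeries, ensemble_stats,
                           mean_field_fixed_point, mean_field_trajectory,
                           mean_field_weekly, simulate_exact,
                           simulate_langevin)
from edcrowd.params import DAY_GROUPS, WeeklyArrivalProfile

from conftest import const_params


def flat(f):
    return WeeklyArrivalProfile(np.full(168, float(f)))


class TestMeanField:
    def test_fixed_point_values(self):
        assert mean_field_fixed_point(14, 1.784 / 7) == pytest.approx(54.93,
                                                                      abs=0.01)
        assert mean_field_fixed_point(0, 0.25) == 0.0
        # linear in the flux
        assert mean_field_fixed_point(28, 1.784 / 7) == pytest.approx(
            2 * mean_field_fixed_point(14, 1.784 / 7))

    def test_fixed_point_rejects_nonpositive_beta(self):
        with pytest.raises(ValueError):
            mean_field_fixed_point(14, 0.0)

    def test_pure_exponential_decay(self):
        traj = mean_field_trajectory(flat(0), const_params(0.25), 100,
                                     np.linspace(0, 4, 9))
        assert traj.counts[-1] == pytest.approx(100 * np.exp(-1))

    def test_fixed_point_is_stationary(self):
        traj = mean_field_trajectory(flat(14), const_params(0.25), 56,
                                     np.arange(0, 100.0))
        assert np.allclose(traj.counts, 56.0)

    def test_relaxation_to_reference_mean(self):
        # constant f=14 with the day-weighted mean exit rate relaxes to ~55
        traj = mean_field_trajectory(flat(14), const_params(1.784 / 7), 0,
                                     np.arange(0, 168.0))
        assert traj.counts[-1] == pytest.approx(54.93, abs=0.05)

    def test_mean_linearity_in_flux(self, calibrated_profile, ref_params):
        grid = np.arange(0, 168.0)
        base = mean_field_trajectory(calibrated_profile, ref_params, 0, grid)
        scaled = mean_field_trajectory(calibrated_profile.scaled(3.0),
                                       ref_params, 0, grid)
        assert np.allclose(scaled.counts, 3.0 * base.counts)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mean_field_trajectory(flat(14), const_params(), -1, [0, 1])
        with pytest.raises(ValueError):
            mean_field_trajectory(flat(14), const_params(), 10, [])


class TestExactSimulator:
    def test_no_flux_no_patients_stays_empty(self):
        out = simulate_exact(flat(0), const_params(), 0, 48, seed=0)
        assert np.all(out.counts == 0)

    def test_stationary_law_is_poisson(self):
        # M/M/inf with f=14, beta=0.25: stationary occupancy ~ Poisson(56)
        out = simulate_exact(flat(14), const_params(0.25), 56, 30_000, seed=1)
        samples = out.counts[200:].astype(int)  # drop transient
        assert samples.mean() == pytest.approx(56, rel=0.02)
        assert samples.var() / samples.mean() == pytest.approx(1.0, abs=0.08)
        support = np.arange(samples.min(), samples.max() + 1)
        empirical = np.bincount(samples - samples.min()) / samples.size
        assert kl_divergence((support, empirical),
                             (support, stats.poisson.pmf(support, 56)),
                             pseudocount=0.5) < 0.01

    def test_pure_death_mean_absorption_time(self):
        # starting at n0=5 with f=0: E[time to empty] = sum_{k=1..5} 1/(beta k)
        beta, n0, reps = 0.5, 5, 10_000
        expected = sum(1 / (beta * k) for k in range(1, n0 + 1))
        rng_seeds = range(reps)
        total = 0.0
        for s in rng_seeds:
            ev = simulate_exact(flat(0), const_params(beta), n0, 60,
                                seed=s, record="events")
            total += ev.times[np.flatnonzero(ev.counts == 0)[0]]
        assert total / reps == pytest.approx(expected, rel=0.03)

    def test_rejects_systematic_noise(self):
        with pytest.raises(ValueError):
            simulate_exact(flat(14), const_params(sigma2=0.3), 10, 10)


class TestLangevin:
    def test_noise_free_limit_matches_closed_form(self, calibrated_profile,
                                                  ref_params):
        params = ref_params.replace(sigma1=0.0, sigma2=0.0)
        (traj,) = simulate_langevin(calibrated_profile, params, 10.0, 168,
                                    dt=0.01, n_realizations=1, seed=0)
        exact = mean_field_trajectory(calibrated_profile, params, 10.0,
                                      traj.times)
        rel = np.abs(traj.counts[1:] - exact.counts[1:]) / exact.counts[1:]
        assert rel.max() < 10 * 0.01

    def test_dt_refinement_converges(self, calibrated_profile, ref_params):
        # halving dt moves the hourly ensemble means by well under 0.5%
        means = []
        for dt in (0.01, 0.005):
            ens = simulate_langevin(calibrated_profile, ref_params, 55.0,
                                    168, dt=dt, n_realizations=4000, seed=9)
            stats_ = ensemble_stats(ens)
            means.append(stats_.mean[24:])  # drop the shared transient
        rel = np.abs(means[0] - means[1]) / means[1]
        assert rel.mean() < 0.005

    def test_matches_exact_birth_death_at_stationarity(self):
        # oracle equivalence: demographic noise only, constant rates
        params = const_params(0.25, sigma1=1.0, sigma2=0.0)
        exact = simulate_exact(flat(14), params, 56, 100_000, seed=3)
        ex_samples = exact.counts[200:]
        lg = simulate_langevin(flat(14), params, 56.0, 268, dt=0.01,
                               n_realizations=600, seed=4)
        lg_samples = np.concatenate([r.counts[100:] for r in lg])
        assert lg_samples.size >= 100_000 and ex_samples.size >= 99_000
        hist = lambda x: np.unique(np.rint(x).astype(int), return_counts=True)
        assert kl_divergence(hist(ex_samples), hist(lg_samples),
                             pseudocount=0.5) < 0.02

    def test_systematic_noise_widens_the_distribution(self):
        base = const_params(0.25, sigma1=1.0, sigma2=0.0)
        noisy = const_params(0.25, sigma1=1.0, sigma2=0.36)
        var = {}
        for name, p in [("base", base), ("noisy", noisy)]:
            ens = simulate_langevin(flat(14), p, 56.0, 168, dt=0.01,
                                    n_realizations=1500, seed=5)
            var[name] = ensemble_stats(ens).std[48:] ** 2
        assert var["noisy"].mean() > 1.3 * var["base"].mean()

    def test_seed_determinism_and_non_negativity(self, calibrated_profile,
                                                 ref_params):
        a = simulate_langevin(calibrated_profile, ref_params, 0.0, 72,
                              n_realizations=3, seed=42)
        b = simulate_langevin(calibrated_profile, ref_params, 0.0, 72,
                              n_realizations=3, seed=42)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.counts, rb.counts)
        # harsh regime: tiny flux, strong noise -- still no negative counts
        harsh = const_params(1.0, sigma1=2.0, sigma2=1.0)
        for r in simulate_langevin(flat(0.5), harsh, 0.0, 168,
                                   n_realizations=20, seed=6):
            assert np.all(r.counts >= 0)

    def test_invalid_dt(self, flat_profile):
        with pytest.raises(ValueError):
            simulate_langevin(flat_profile, const_params(), 10, 24, dt=-0.1)


class TestEnsembleStats:
    def test_identical_realizations_have_zero_std(self):
        t = np.arange(5.0)
        series = [OccupancySeries(t, np.full(5, 7.0))] * 4
        out = ensemble_stats(series)
        assert np.all(out.std == 0)
        assert out.histogram[1].sum() == pytest.approx(1.0)

    def test_hand_computed_mean_and_std(self):
        t = np.array([0.0, 1.0])
        series = [OccupancySeries(t, np.array([50.0, 50.0])),
                  OccupancySeries(t, np.array([60.0, 60.0]))]
        out = ensemble_stats(series)
        assert np.allclose(out.mean, 55.0)
        assert np.allclose(out.std, 5.0)  # population STD

    def test_poisson_mean_equals_variance_at_stationarity(self):
        runs = [simulate_exact(flat(14), const_params(0.25), 56, 60, seed=s)
                for s in range(400)]
        out = ensemble_stats(runs)
        late = slice(40, None)  # past the transient
        ratio = out.std[late] ** 2 / out.mean[late]
        assert ratio.mean() == pytest.approx(1.0, abs=0.15)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            ensemble_stats([])

    def test_resampling_onto_common_grid(self):
        a = OccupancySeries(np.array([0.0, 1.0, 2.0]),
                            np.array([1.0, 3.0, 5.0]))
        b = OccupancySeries(np.array([0.0, 0.5, 2.0]),
                            np.array([2.0, 4.0, 6.0]))
        out = ensemble_stats([a, b], sample_times=[0.75, 2.0])
        # previous-value interpolation: a -> (1, 5), b -> (4, 6)
        assert np.allclose(out.mean, [2.5, 5.5])


def test_occupancy_series_validation():
    with pytest.raises(ValueError):
        OccupancySeries(np.array([0.0, 0.0]), np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        OccupancySeries(np.array([0.0, 1.0]), np.array([1.0, -2.0]))


def test_mean_field_weekly_is_periodic(calibrated_profile, ref_params):
    weekly = mean_field_weekly(calibrated_profile, ref_params)
    two = mean_field_trajectory(calibrated_profile, ref_params,
                                weekly.counts[0], np.arange(0, 336.0))
    assert np.allclose(two.counts[:168], two.counts[168:], rtol=1e-9)
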