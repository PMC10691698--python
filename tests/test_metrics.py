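import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edcrowd.metrics import (ShiftSummary, hourly_flux, hourly_occupancy,
                             kl_divergence, occupancy_from_log,
                             patient_hours, patient_hours_from_log,
                             r_squared, relative_crowding, shift_summaries,
                             survival_curve)
from edcrowd.model import OccupancySeries
from edcrowd.params import WeeklyArrivalProfile
from edcrowd.synth import VisitLog, generate_visit_log

from conftest import const_params


def make_log(intervals, n_weeks=1):
    """VisitLog from explicit (arrival, departure) hour pairs."""
    if intervals:
        arr, dep = map(np.asarray, zip(*intervals))
    else:
        arr = dep = np.array([])
    return VisitLog(arrivals_h=arr.astype(float),
                    departures_h=dep.astype(float), n_weeks=n_weeks)


class TestOccupancy:
    def test_half_open_membership(self):
        log = make_log([(1.0, 5.0)])  # 08:00 -> 12:00 on day 1
        out = occupancy_from_log(log, [2.0, 5.0])
        assert list(out.counts) == [1, 0]

    def test_hand_counted_overlaps(self):
        log = make_log([(1.0, 3.0), (2.0, 4.0), (2.5, 5.0)])
        out = occupancy_from_log(log, [2.75, 3.5])
        assert list(out.counts) == [3, 2]

    def test_empty_log_is_zero(self):
        out = occupancy_from_log(make_log([]), np.arange(0.0, 10.0))
        assert np.all(out.counts == 0)

    def test_grid_outside_period_rejected(self):
        with pytest.raises(ValueError):
            occupancy_from_log(make_log([(1.0, 2.0)]), [100.0, 200.0])


class TestHourlyFlux:
    def test_single_arrival_bins_by_own_hour(self):
        log = make_log([(1.5, 3.0)])  # Sunday 08:30
        counts, stats_ = hourly_flux(log, "arrival")
        assert counts[1] == 1 and counts.sum() == 1
        assert stats_.mean[1] == 1

    def test_sums_to_record_count(self, study_log):
        counts, _ = hourly_flux(study_log, "arrival")
        assert counts.sum() == len(study_log)

    def test_flat_poisson_flux_statistics(self):
        prof = WeeklyArrivalProfile(np.full(168, 14.0))
        log = generate_visit_log(prof, const_params(0.25), 100, seed=8)
        _, stats_ = hourly_flux(log, "arrival")
        assert stats_.mean.mean() == pytest.approx(14.0, rel=0.02)
        assert stats_.std.mean() == pytest.approx(np.sqrt(14), rel=0.05)

    def test_arrivals_balance_exits_at_stationarity(self):
        prof = WeeklyArrivalProfile(np.full(168, 14.0))
        log = generate_visit_log(prof, const_params(0.25), 100, seed=9)
        _, arr = hourly_flux(log, "arrival", skip_weeks=2)
        _, ext = hourly_flux(log, "exit", skip_weeks=2)
        assert ext.mean.mean() == pytest.approx(arr.mean.mean(), rel=0.01)

    def test_conservation_identity(self, study_log):
        # occupancy(end) - occupancy(start) = arrivals - exits in the window;
        # occupancy counts arrival <= t, so events balance over (t0, t1]
        for (t0, t1) in [(24.0, 48.0), (100.0, 300.0), (1000.0, 1001.0)]:
            occ = occupancy_from_log(study_log, [t0, t1])
            arr = np.sum((study_log.arrivals_h > t0)
                         & (study_log.arrivals_h <= t1))
            ext = np.sum((study_log.departures_h > t0)
                         & (study_log.departures_h <= t1))
            assert occ.counts[1] - occ.counts[0] == arr - ext


class TestPatientHours:
    def test_printed_worked_example(self):
        # 100 patients present for a whole 8-hour shift -> C = 800
        log = make_log([(0.0, 10.0)] * 100)
        assert patient_hours_from_log(log, (0.0, 8.0)) == pytest.approx(800.0)

    def test_zero_occupancy(self):
        assert patient_hours_from_log(make_log([]), (0.0, 8.0)) == 0.0

    def test_piecewise_constant_integral(self):
        # 50 patients for 4 h, then 30 for 4 h -> C = 320
        log = make_log([(0.0, 4.0)] * 20 + [(0.0, 8.0)] * 30)
        assert patient_hours_from_log(log, (0.0, 8.0)) == pytest.approx(320.0)

    def test_trapezoid_on_sampled_series(self):
        series = OccupancySeries(np.arange(0.0, 9.0), np.full(9, 100.0))
        assert patient_hours(series, (0.0, 8.0)) == pytest.approx(800.0)
        with pytest.raises(ValueError):
            patient_hours(series, (4.0, 12.0))

    def test_equals_sum_of_in_window_durations(self, study_log):
        # independent recomputation: loop over records
        window = (168.0, 176.0)
        total = 0.0
        for a, d in zip(study_log.arrivals_h, study_log.departures_h):
            total += max(0.0, min(d, window[1]) - max(a, window[0]))
        assert patient_hours_from_log(study_log, window) \
            == pytest.approx(total)

    def test_shift_summaries_cover_the_whole_log(self, study_log):
        summaries = shift_summaries(study_log, skip_weeks=1)
        assert len(summaries) == 99 * 21
        keys = {s.shift_key for s in summaries}
        assert len(keys) == 21


class TestRelativeCrowding:
    def test_all_equal_gives_unit_ratio(self):
        base = [ShiftSummary(("Sunday", "morning"), (0, 8), 400.0, w)
                for w in range(4)]
        assert all(s.relative == 1.0 for s in relative_crowding(base))

    def test_hand_computed_ratios(self):
        base = [ShiftSummary(("Sunday", "morning"), (0, 8), c, w)
                for w, c in enumerate((400.0, 480.0))]
        out = relative_crowding(base)
        assert out[0].relative == pytest.approx(400 / 440)
        assert out[1].relative == pytest.approx(480 / 440)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        base = [ShiftSummary(("Monday", "night"), (0, 8), c, w)
                for w, c in enumerate(rng.uniform(200, 600, 10))]
        doubled = [ShiftSummary(s.shift_key, s.window, 2 * s.patient_hours,
                                s.week) for s in base]
        for a, b in zip(relative_crowding(base), relative_crowding(doubled)):
            assert a.relative == pytest.approx(b.relative)

    def test_zero_mean_rejected(self):
        base = [ShiftSummary(("Friday", "morning"), (0, 8), 0.0, 0)]
        with pytest.raises(ZeroDivisionError):
            relative_crowding(base)


class TestSurvival:
    def test_instant_exits(self):
        log = make_log([(1.0, 1.0 + 1 / 60)] * 50)
        times, fractions, beta = survival_curve(log, cohort_start=1.0)
        assert np.all(fractions[times > 0.1] == 0)
        assert np.isnan(beta)  # nothing left to fit a decay to

    def test_monotone_non_increasing(self, study_log):
        _, fractions, _ = survival_curve(study_log, cohort_start=10)
        assert np.all(np.diff(fractions) <= 0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            survival_curve(make_log([(1.0, 2.0)]), cohort_start=50.0)


class TestGoodnessOfFit:
    def test_identical_histograms_have_zero_divergence(self):
        p = np.array([0.2, 0.3, 0.5])
        assert kl_divergence(p, p) == pytest.approx(0.0)

    def test_closed_form_value(self):
        # KL((.5,.5) || (.9,.1)) = .5 ln(5/9) + .5 ln 5
        expected = 0.5 * np.log(0.5 / 0.9) + 0.5 * np.log(0.5 / 0.1)
        assert kl_divergence([0.5, 0.5], [0.9, 0.1]) \
            == pytest.approx(expected)

    def test_union_support_alignment(self):
        p = (np.array([1, 2]), np.array([5, 5]))
        q = (np.array([2, 3]), np.array([5, 5]))
        with pytest.raises(ZeroDivisionError):
            kl_divergence(p, q)
        assert kl_divergence(p, q, pseudocount=0.5) > 0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.integers(1, 50), min_size=2, max_size=12),
           st.lists(st.integers(1, 50), min_size=2, max_size=12))
    def test_divergence_non_negative(self, a, b):
        k = min(len(a), len(b))
        assert kl_divergence(np.array(a[:k], float),
                             np.array(b[:k], float)) >= 0

    def test_r_squared(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(obs, obs) == 1.0
        assert r_squared(obs, np.full(4, obs.mean())) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            r_squared(np.full(3, 2.0), obs[:3])


def test_hourly_occupancy_week_reshape(study_log):
    series, stats_ = hourly_occupancy(study_log, skip_weeks=1)
    assert series.counts.size == 100 * 168
    assert stats_.n_obs == 99
    assert stats_.mean.shape == (168,)
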