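"""Tests for the penalized cost, bootstrap machinery, and fitting."""

import dataclasses

import numpy as np
import pytest

from psadyn import (
    DailyTransition,
    ExplicitSchedule,
    FitConfig,
    PSASeries,
    constraint_penalties,
    cost,
    fit_ensemble,
    fit_single,
    penalty_h,
    resample_indices,
    simulate,
    truncate_cycles,
)
from psadyn.synthetic_cohort import CohortConfig, draw_parameters, generate_patient
from psadyn.classification import PatientType
from conftest import make_series


class TestPenaltyH:
    @pytest.mark.parametrize(
        "z,expected", [(0.5, 0.0), (0.0, 0.0), (-0.01, 101.0), (-1.0, 200.0)]
    )
    def test_printed_values(self, z, expected):
        assert penalty_h(z) == pytest.approx(expected)

    def test_non_negative_and_non_increasing(self):
        z = np.linspace(-3, 3, 1001)
        h = penalty_h(z)
        assert np.all(h >= 0)
        assert np.all(np.diff(h) <= 0)
        assert np.all(h[z >= 0] == 0)


def _trajs(d, x0, series):
    traj = simulate(d, x0, ExplicitSchedule(series.on_vector()), series.span_end)
    traj_cas = simulate(d, x0, ExplicitSchedule(np.ones(1800, dtype=np.int8)), 1800)
    return traj, traj_cas


class TestConstraintPenalties:
    def setup_method(self):
        self.series = make_series(
            [0, 30, 80], [5.0, 3.0, 1.5], [(0, 60, True), (60, 100, False)]
        )

    def _penalty(self, d, x0=(4.0, 0.8, 0.2)):
        traj, traj_cas = _trajs(d, np.asarray(x0), self.series)
        return constraint_penalties(d, traj, traj_cas, obs_days=self.series.times)

    def test_feasible_set_with_relapsing_cas_has_zero_penalty(self):
        cfg = CohortConfig(seed=0)
        d, x0 = draw_parameters(PatientType.TYPE_II, 3, cfg)
        traj, traj_cas = _trajs(d, x0.as_array(), self.series)
        assert constraint_penalties(d, traj, traj_cas, self.series.times) == 0.0

    def test_single_box_violation_value(self, feasible_d):
        """Lowering d1_11 to 0.7 with an x3-only initial state (so the
        trajectories are unaffected) adds exactly the parameter-box terms:
        h(0.7 - 0.8) = 110 plus the on-column sum 0.76 < 0.8 giving
        h(-0.04) = 104."""
        x0 = (0.0, 0.0, 2.0)
        d_ref = dataclasses.replace(feasible_d, d1_33=1.0, d0_33=1.0)
        good = self._penalty(d_ref, x0)
        bad = self._penalty(dataclasses.replace(d_ref, d1_11=0.7), x0)
        assert bad - good == pytest.approx(110.0 + 104.0)

    def test_cas_relapse_shortfall_value(self):
        """A continuous-suppression PSA of 9 ng/ml at day 1800 contributes
        100 * (1 - (9 - 10)) = 200."""
        d = DailyTransition.from_vector([1, 0, 1, 0, 0, 1, 1, 0, 1, 1])
        x0 = np.array([0.0, 0.0, 9.0])  # constant CAS trajectory at 9 ng/ml
        traj, traj_cas = _trajs(d, x0, self.series)
        total = constraint_penalties(d, traj, traj_cas, self.series.times)
        # identity dynamics also trip PSA(360) <= 2: h(2 - 9) = 100 * 8 = 800
        assert total == pytest.approx(200.0 + 800.0)


class TestCost:
    def setup_method(self):
        self.config = FitConfig()
        cfg = CohortConfig(seed=0)
        self.d, self.x0 = draw_parameters(PatientType.TYPE_II, 3, cfg)

    def _noiseless_series(self, times, intervals):
        traj = simulate(
            self.d, self.x0, ExplicitSchedule(
                PSASeries("t", [0], [1.0], intervals).on_vector(max(times))
            ), max(times)
        )
        return make_series(times, traj.psa[np.asarray(times)], intervals)

    def test_perfect_fit_hits_cost_floor(self):
        times = [0, 50, 150, 250, 350, 500]
        series = self._noiseless_series(times, [(0, 300, True), (300, 600, False)])
        c = cost(self.d, self.x0, series, np.arange(series.K), self.config)
        floor = self.config.eps2 / (series.K + self.config.eps1)
        assert c == pytest.approx(floor, abs=1e-15)

    def test_single_observation_residual(self):
        series = make_series([10], [5.0], [(0, 20, True)])
        traj = simulate(self.d, self.x0, ExplicitSchedule(np.ones(20)), 20)
        resid = abs(5.0 - traj.psa[10])
        c = cost(self.d, self.x0, series, [0], self.config)
        expected_data = (resid + 0.001) / (1 + 1e-9)
        assert c == pytest.approx(expected_data, abs=1e-12)

    def test_duplicated_index_adds_residual_once_more(self):
        times = [0, 100, 200, 300]
        series = make_series(
            times, [6.0, 2.0, 1.0, 3.0], [(0, 150, True), (150, 350, False)]
        )
        base = cost(self.d, self.x0, series, [0, 1, 2, 3], self.config)
        doubled = cost(self.d, self.x0, series, [0, 1, 2, 2], self.config)
        traj = simulate(self.d, self.x0, ExplicitSchedule(series.on_vector()), 350)
        r2 = abs(1.0 - traj.psa[200])
        r3 = abs(3.0 - traj.psa[300])
        assert doubled - base == pytest.approx((r2 - r3) / (4 + 1e-9), abs=1e-10)

    def test_cost_invariant_to_resample_order(self):
        times = [0, 100, 200, 300]
        series = make_series(
            times, [6.0, 2.0, 1.0, 3.0], [(0, 150, True), (150, 350, False)]
        )
        a = cost(self.d, self.x0, series, [3, 0, 2, 1], self.config)
        b = cost(self.d, self.x0, series, [0, 1, 2, 3], self.config)
        assert a == b

    def test_out_of_range_index_rejected(self):
        series = make_series([10], [5.0], [(0, 20, True)])
        with pytest.raises(IndexError):
            cost(self.d, self.x0, series, [1], self.config)


class TestResampling:
    def test_single_point_series_resamples_itself(self):
        assert resample_indices(1, 0).tolist() == [0]

    def test_zero_points_rejected(self):
        with pytest.raises(ValueError):
            resample_indices(0, 0)

    def test_deterministic_given_seed(self):
        a = resample_indices(50, 123)
        b = resample_indices(50, 123)
        assert np.array_equal(a, b)

    def test_bootstrap_inclusion_fraction(self):
        """Mean fraction of distinct indices over many resamples matches
        1 - (1 - 1/K)^K (~0.636 for K = 50)."""
        K, n = 50, 10_000
        rng = np.random.default_rng(7)
        draws = rng.integers(0, K, size=(n, K))
        distinct = np.array([len(np.unique(row)) for row in draws]) / K
        expected = 1 - (1 - 1 / K) ** K
        assert distinct.mean() == pytest.approx(expected, abs=0.01)


class TestTruncateCycles:
    def _series(self, n_interval_pairs, extra_on=True):
        intervals = []
        t = 0
        for _ in range(n_interval_pairs):
            intervals.append((t, t + 100, True))
            intervals.append((t + 100, t + 200, False))
            t += 200
        if extra_on:
            intervals.append((t, t + 100, True))
        span = intervals[-1][1]
        times = np.arange(10, span, 60)
        return make_series(times, np.linspace(10, 1, len(times)), intervals)

    def test_exactly_two_and_a_half_cycles_unchanged(self):
        s = self._series(2, extra_on=True)
        assert truncate_cycles(s) is s

    def test_five_cycles_truncated_at_third_on_interval(self):
        s = self._series(5, extra_on=False)
        t = truncate_cycles(s)
        assert t.span_end == 500
        assert t.n_on_intervals() == 3
        assert t.times.max() <= 500
        assert t.K < s.K

    def test_single_cycle_returned_with_warning_flag(self):
        s = self._series(1, extra_on=False)
        t = truncate_cycles(s)
        assert "short_window" in t.flags
        assert np.array_equal(t.times, s.times)


class TestFitting:
    def test_identical_seeds_give_identical_results(self, two_cycle_series):
        cfg = FitConfig(population=10, max_generations=15, seed=5)
        idx = resample_indices(two_cycle_series.K, 5)
        a = fit_single(two_cycle_series, idx, cfg)
        b = fit_single(two_cycle_series, idx, cfg)
        assert a == b

    def test_resample_order_does_not_change_fit(self, two_cycle_series):
        cfg = FitConfig(population=10, max_generations=15, seed=5)
        idx = resample_indices(two_cycle_series.K, 5)
        a = fit_single(two_cycle_series, idx, cfg)
        b = fit_single(two_cycle_series, idx[::-1], cfg)
        assert a.cost == pytest.approx(b.cost)

    def test_degenerate_single_point_series(self):
        series = make_series([5], [3.0], [(0, 10, True)])
        cfg = FitConfig(population=10, max_generations=10, seed=1)
        res = fit_single(series, [0], cfg)
        assert res.cost >= cfg.eps2 / (1 + cfg.eps1)

    def test_noiseless_recovery_with_default_budget(self):
        """On noiseless data from feasible well-separated parameters the
        fitted trajectory reproduces the observations to <= 0.5 ng/ml MAE."""
        cohort = CohortConfig(seed=11, noise_sigma=0.0)
        d, x0 = draw_parameters(PatientType.TYPE_I, 11, cohort)
        patient = generate_patient(d, x0, cohort, 12, "N", PatientType.TYPE_I)
        window = truncate_cycles(patient.series)
        res = fit_single(window, np.arange(window.K), FitConfig(seed=2))
        traj = simulate(
            res.d, res.x0, ExplicitSchedule(window.on_vector()), window.span_end
        )
        mae = np.mean(np.abs(traj.psa[window.times] - window.psa))
        assert mae <= 0.5

    def test_ensemble_reproducible_and_flags_consistent(self, two_cycle_series):
        cfg = FitConfig(population=10, max_generations=10, seed=9)
        e1 = fit_ensemble(two_cycle_series, B=3, config=cfg)
        e2 = fit_ensemble(two_cycle_series, B=3, config=cfg)
        assert e1.members == e2.members
        assert e1.B == 3
        for m, acc in zip(e1.members, e1.accepted):
            assert acc == (m.end_error <= 5.0)
        assert {m.seed for m in e1.members} == {9, 10, 11}

    def test_single_member_ensemble_matches_fit_single(self, two_cycle_series):
        cfg = FitConfig(population=10, max_generations=10, seed=4)
        ens = fit_ensemble(two_cycle_series, B=1, config=cfg)
        idx = resample_indices(two_cycle_series.K, 4)
        direct = fit_single(two_cycle_series, idx, cfg)
        assert ens.members[0] == direct
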