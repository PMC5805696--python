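"""Tests for the treatment protocols and the robust exhaustive optimizer.

The optimizer oracle: for diagonal members every compartment evolves as a
product of scalar powers, so each candidate block schedule's horizon PSA
has a closed form.  The oracle enumerates schedules with plain Python
floats, independent of the package's matrix simulation path.
"""

import itertools

import numpy as np
import pytest

from psadyn import (
    BlockSchedule,
    BootstrapEnsemble,
    CellState,
    DailyTransition,
    ExplicitSchedule,
    FitResult,
    ScheduleSearchConfig,
    cas,
    conventional_ias,
    optimize_mean_dynamics,
    optimize_schedule,
    time_under_threshold,
    worst_case_objective,
)
from conftest import diagonal_d


def member(d: DailyTransition, end_state, err=0.0) -> FitResult:
    s = CellState.from_array(np.asarray(end_state, dtype=float))
    return FitResult(
        d=d, x0=s, cost=0.0, end_error=err, end_state=s,
        replicate=0, seed=0, converged=True,
    )


def ensemble(*members_and_flags) -> BootstrapEnsemble:
    members = [m for m, _ in members_and_flags]
    flags = [f for _, f in members_and_flags]
    return BootstrapEnsemble("T", tuple(members), tuple(flags))


def oracle_horizon_psa(d: DailyTransition, x0, blocks, block_days, horizon):
    """Closed-form horizon PSA for a diagonal member under a block schedule."""
    on = [d.d1_11, d.d1_22, d.d1_33]
    off = [d.d0_11, d.d0_22, d.d0_33]
    state = list(x0)
    remaining = horizon
    for b in blocks:
        n = min(block_days, remaining)
        state = [
            s * ((on[i] if b else off[i]) ** n) for i, s in enumerate(state)
        ]
        remaining -= n
        if remaining == 0:
            break
    return sum(state)


def oracle_best(members, config):
    n = -(-config.horizon // config.block_days)
    best = None
    for blocks in itertools.product((0, 1), repeat=n):
        worst = max(
            oracle_horizon_psa(m.d, m.end_state.as_array(), blocks,
                               config.block_days, config.horizon)
            for m in members
        )
        key = (worst, -sum(blocks), blocks)
        if best is None or key < best:
            best = key
    return best[0], best[2]


class TestProtocols:
    def test_cas_equals_all_on_explicit(self, feasible_d):
        a = cas(feasible_d, [5, 1, 0.2], 100)
        b_sched = ExplicitSchedule(np.ones(100, dtype=np.int8))
        from psadyn import simulate

        b = simulate(feasible_d, [5, 1, 0.2], b_sched, 100)
        assert np.array_equal(a.states, b.states)

    def test_cas_identity_dynamics_constant(self, identity_d):
        traj = cas(identity_d, [1, 1, 1], 50)
        assert np.allclose(traj.psa, 3.0)

    def test_conventional_never_stops_before_280_on_days(self):
        d = diagonal_d((0.9, 0.9, 0.9), (1.05, 1.05, 1.05))
        traj = conventional_ias(d, [10.0, 0, 0], 2000)
        on = traj.on
        starts = [0] + (np.flatnonzero((on[1:] == 1) & (on[:-1] == 0)) + 1).tolist()
        stops = (np.flatnonzero((on[1:] == 0) & (on[:-1] == 1)) + 1).tolist()
        for stop in stops:
            start = max(s for s in starts if s <= stop)
            assert stop - start >= 280


class TestWorstCase:
    def test_single_member_objective(self):
        d = diagonal_d((1.01, 1, 1), (0.99, 1, 1))
        m = member(d, [2.0, 0, 0])
        cfg = ScheduleSearchConfig(horizon=100, block_days=50)
        sched = BlockSchedule(50, (1, 1))
        obj = worst_case_objective(sched, ensemble((m, True)), cfg)
        assert obj == pytest.approx(2.0 * 1.01 ** 100, rel=1e-9)

    def test_max_over_two_diagonal_members(self):
        fast = member(diagonal_d((1.02, 1, 1), (1.02, 1, 1)), [1.0, 0, 0])
        slow = member(diagonal_d((1.0, 1, 1), (1.0, 1, 1)), [1.0, 0, 0])
        cfg = ScheduleSearchConfig(horizon=100, block_days=100)
        sched = BlockSchedule(100, (1,))
        both = worst_case_objective(sched, ensemble((fast, True), (slow, True)), cfg)
        assert both == pytest.approx(1.02 ** 100, rel=1e-9)

    def test_adding_dominated_member_leaves_objective(self):
        fast = member(diagonal_d((1.02, 1, 1), (1.02, 1, 1)), [1.0, 0, 0])
        slow = member(diagonal_d((0.99, 1, 1), (0.99, 1, 1)), [1.0, 0, 0])
        cfg = ScheduleSearchConfig(horizon=100, block_days=100)
        sched = BlockSchedule(100, (1,))
        assert worst_case_objective(
            sched, ensemble((fast, True), (slow, True)), cfg
        ) == worst_case_objective(sched, ensemble((fast, True)), cfg)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            worst_case_objective(
                BlockSchedule(10, (1,)),
                BootstrapEnsemble("T", (), ()),
                ScheduleSearchConfig(horizon=10, block_days=10),
            )

    def test_fallback_to_best_member_when_none_accepted(self):
        m = member(diagonal_d((1.0, 1, 1), (1.0, 1, 1)), [3.0, 0, 0], err=9.0)
        cfg = ScheduleSearchConfig(horizon=10, block_days=10)
        obj = worst_case_objective(BlockSchedule(10, (1,)), ensemble((m, False)), cfg)
        assert obj == pytest.approx(3.0)


class TestOptimizer:
    def test_on_decay_off_growth_prefers_all_on(self):
        d = diagonal_d((0.99, 0.99, 0.99), (1.01, 1.01, 1.01))
        cfg = ScheduleSearchConfig(horizon=300, block_days=100)
        res = optimize_schedule(ensemble((member(d, [1, 1, 1]), True)), cfg)
        assert res.blocks == (1, 1, 1)
        assert res.n_evaluated == 8

    def test_on_growth_off_decay_prefers_all_off(self):
        d = diagonal_d((1.01, 1.01, 1.01), (0.99, 0.99, 0.99))
        cfg = ScheduleSearchConfig(horizon=300, block_days=100)
        res = optimize_schedule(ensemble((member(d, [1, 1, 1]), True)), cfg)
        assert res.blocks == (0, 0, 0)

    def test_block_guard_rejects_huge_searches(self):
        cfg = ScheduleSearchConfig(horizon=10_000, block_days=10)
        with pytest.raises(ValueError):
            optimize_schedule(
                ensemble((member(diagonal_d((1, 1, 1), (1, 1, 1)), [1, 1, 1]), True)),
                cfg,
            )

    def test_matches_brute_force_oracle_on_random_ensembles(self):
        """Note: diagonal members commute, so schedules differing only in
        the order of their full on-blocks tie exactly; the check is that the
        returned schedule is oracle-optimal and the objectives agree."""
        rng = np.random.default_rng(31)
        cfg = ScheduleSearchConfig(horizon=1080, block_days=168)
        for _ in range(5):
            members = [
                member(
                    diagonal_d(rng.uniform(0.98, 1.02, 3), rng.uniform(0.98, 1.02, 3)),
                    rng.uniform(0.5, 5.0, 3),
                )
                for _ in range(2)
            ]
            res = optimize_schedule(ensemble(*[(m, True) for m in members]), cfg)
            best_obj, best_blocks = oracle_best(members, cfg)
            assert res.worst_case_psa == pytest.approx(best_obj, rel=1e-9)
            chosen_in_oracle = max(
                oracle_horizon_psa(m.d, m.end_state.as_array(), res.blocks,
                                   cfg.block_days, cfg.horizon)
                for m in members
            )
            assert chosen_in_oracle == pytest.approx(best_obj, rel=1e-12)

    def test_objective_bounded_by_constant_schedules(self):
        rng = np.random.default_rng(5)
        cfg = ScheduleSearchConfig(horizon=500, block_days=100)
        members = [
            member(
                diagonal_d(rng.uniform(0.97, 1.03, 3), rng.uniform(0.97, 1.03, 3)),
                rng.uniform(0.5, 3.0, 3),
            )
            for _ in range(3)
        ]
        ens = ensemble(*[(m, True) for m in members])
        res = optimize_schedule(ens, cfg)
        n = cfg.n_blocks
        assert res.worst_case_psa <= worst_case_objective(
            BlockSchedule(cfg.block_days, (1,) * n), ens, cfg
        ) + 1e-12
        assert res.worst_case_psa <= worst_case_objective(
            BlockSchedule(cfg.block_days, (0,) * n), ens, cfg
        ) + 1e-12

    def test_reported_objective_recomputable_from_schedule(self):
        rng = np.random.default_rng(9)
        cfg = ScheduleSearchConfig(horizon=500, block_days=100)
        members = [
            member(
                diagonal_d(rng.uniform(0.97, 1.03, 3), rng.uniform(0.97, 1.03, 3)),
                rng.uniform(0.5, 3.0, 3),
            )
            for _ in range(2)
        ]
        ens = ensemble(*[(m, True) for m in members])
        res = optimize_schedule(ens, cfg)
        assert worst_case_objective(res.schedule(), ens, cfg) == res.worst_case_psa


class TestMeanDynamics:
    def test_single_member_matches_worst_case_search(self):
        d = diagonal_d((1.005, 0.99, 1.0), (0.995, 1.01, 1.0))
        cfg = ScheduleSearchConfig(horizon=300, block_days=100)
        ens = ensemble((member(d, [1, 0.5, 0.2]), True))
        robust = optimize_schedule(ens, cfg)
        mean = optimize_mean_dynamics(ens, cfg)
        assert mean.blocks == robust.blocks
        assert mean.worst_case_psa == pytest.approx(robust.worst_case_psa)
        assert mean.mean_dynamics

    def test_identical_members_average_to_themselves(self):
        d = diagonal_d((1.005, 0.99, 1.0), (0.995, 1.01, 1.0))
        cfg = ScheduleSearchConfig(horizon=300, block_days=100)
        one = optimize_schedule(ensemble((member(d, [1, 1, 1]), True)), cfg)
        two = optimize_mean_dynamics(
            ensemble((member(d, [1, 1, 1]), True), (member(d, [1, 1, 1]), True)), cfg
        )
        assert one.blocks == two.blocks

    def test_mean_dynamics_is_more_optimistic_than_worst_case(self):
        """With one benign and one aggressive member, the mean system's
        reported objective understates the worst case of its own schedule."""
        benign = member(diagonal_d((0.98, 1, 1), (0.98, 1, 1)), [1.0, 0, 0])
        aggressive = member(diagonal_d((1.02, 1, 1), (1.02, 1, 1)), [1.0, 0, 0])
        cfg = ScheduleSearchConfig(horizon=300, block_days=100)
        ens = ensemble((benign, True), (aggressive, True))
        mean = optimize_mean_dynamics(ens, cfg)
        assert worst_case_objective(
            BlockSchedule(cfg.block_days, mean.blocks), ens, cfg
        ) >= mean.worst_case_psa


class TestTimeUnderThreshold:
    def test_flat_members_censored_at_horizon(self, identity_d):
        cfg = ScheduleSearchConfig(horizon=200, block_days=100)
        ens = ensemble((member(identity_d, [5, 0, 0]), True))
        day, censored = time_under_threshold(ens, BlockSchedule(100, (1, 1)), cfg)
        assert (day, censored) == (200, True)

    def test_geometric_crossing_day(self, identity_d):
        """One member growing as 50 * 1.01^t crosses 100 at day 70."""
        grower = member(diagonal_d((1.01, 1, 1), (1.01, 1, 1)), [50.0, 0, 0])
        flat = member(identity_d, [5, 0, 0])
        cfg = ScheduleSearchConfig(horizon=200, block_days=200)
        ens = ensemble((grower, True), (flat, True))
        day, censored = time_under_threshold(ens, BlockSchedule(200, (1,)), cfg)
        assert not censored
        assert day == int(np.ceil(np.log(2.0) / np.log(1.01)))

    def test_extra_member_cannot_delay_crossing(self, identity_d):
        cfg = ScheduleSearchConfig(horizon=300, block_days=300)
        sched = BlockSchedule(300, (1,))
        grower = member(diagonal_d((1.01, 1, 1), (1.01, 1, 1)), [50.0, 0, 0])
        faster = member(diagonal_d((1.03, 1, 1), (1.03, 1, 1)), [50.0, 0, 0])
        base, _ = time_under_threshold(ens := ensemble((grower, True)), sched, cfg)
        more, _ = time_under_threshold(
            ensemble((grower, True), (faster, True)), sched, cfg
        )
        assert more <= base
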