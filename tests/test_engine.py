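import numpy as np
import pytest

import mrcosim as m
from mrcosim.engine import (
    Component,
    EngineConfig,
    MultirateEngine,
    align_macro_end,
    exchange_at,
    gating_violations,
    order_components,
    solve_adaptive,
)


def make_component(cid, h_pred, **kwargs):
    c = Component(cid, lambda t, x, u: -x, [1.0], **kwargs)
    c.initialize(0.0)
    c.h_pred = h_pred
    return c


class TestOrderComponents:
    def test_sorted_slowest_first(self):
        a = make_component("A", 1e-1)
        b = make_component("B", 1e-4)
        ordered, switched = order_components([b, a])
        assert [c.id for c in ordered] == ["A", "B"]
        assert switched is False  # no previous order

    def test_unchanged_order_is_not_a_switch(self):
        a = make_component("A", 1e-4)
        b = make_component("B", 1e-1)
        ordered, switched = order_components([a, b], previous_order=["B", "A"])
        assert [c.id for c in ordered] == ["B", "A"]
        assert not switched

    def test_equal_steps_stable(self):
        a = make_component("A", 1e-3)
        b = make_component("B", 1e-3)
        ordered, _ = order_components([a, b])
        assert [c.id for c in ordered] == ["A", "B"]

    def test_change_counts_as_switch(self):
        a = make_component("A", 1e-1)
        b = make_component("B", 1e-4)
        _, switched = order_components([a, b], previous_order=["B", "A"])
        assert switched


class TestExchangeAt:
    def _source_with_samples(self, fn, times):
        src = Component("src", lambda t, x, u: x, [0.0])
        src.initialize(times[0])
        src.exchange.times = []
        src.exchange.values = []
        for t in times:
            src.exchange.append(t, [fn(t)])
        return src

    def test_quadratic_extrapolation_exact(self):
        src = self._source_with_samples(lambda t: t * t, [0.0, 0.5, 1.0])
        tgt = Component("tgt", lambda t, x, u: x, [0.0])
        value, cls = exchange_at(tgt, src, 2.0)
        assert value[0] == pytest.approx(4.0, rel=1e-12)
        assert cls == "extrapolation"

    def test_stored_sample_returned_at_node(self):
        src = self._source_with_samples(lambda t: np.sin(t), [0.0, 0.4, 1.0])
        tgt = Component("tgt", lambda t, x, u: x, [0.0])
        value, cls = exchange_at(tgt, src, 0.4)
        assert value[0] == pytest.approx(np.sin(0.4), rel=1e-14)
        assert cls == "interpolation"

    def test_empty_source_rejected(self):
        src = Component("src", lambda t, x, u: x, [0.0])
        src.initialize(0.0)
        src.exchange.times = []
        src.exchange.values = []
        tgt = Component("tgt", lambda t, x, u: x, [0.0])
        with pytest.raises(m.EngineError):
            exchange_at(tgt, src, 0.5)


class TestAlignMacroEnd:
    def test_async_linear_interpolation_at_macro_end(self):
        fast = Component("fast", lambda t, x, u: x, [0.0])
        fast.initialize(0.0)
        fast.exchange.times = []
        fast.exchange.values = []
        for t in (0.8, 1.05):
            fast.exchange.append(t, [t])  # u(t) = t
        assert align_macro_end(fast, 1.0, "asynchronous")[0] == pytest.approx(1.0)

    def test_async_quadratic_exact(self):
        fast = Component("fast", lambda t, x, u: x, [0.0])
        fast.initialize(0.0)
        fast.exchange.times = []
        fast.exchange.values = []
        for t in (0.7, 0.9, 1.1):
            fast.exchange.append(t, [t * t])
        assert align_macro_end(fast, 1.0, "asynchronous")[0] == pytest.approx(1.0, rel=1e-12)

    def test_sync_requires_exact_landing(self):
        fast = Component("fast", lambda t, x, u: x, [0.0])
        fast.initialize(0.0)
        fast.exchange.append(0.5, [1.0])
        with pytest.raises(m.EngineError):
            align_macro_end(fast, 1.0, "synchronous")

    def test_not_reached_is_invariant_violation(self):
        fast = Component("fast", lambda t, x, u: x, [0.0])
        fast.initialize(0.0)
        with pytest.raises(m.EngineError):
            align_macro_end(fast, 1.0, "asynchronous")


class TestDegenerateRecursion:
    def test_single_component_bitwise_equals_standalone(self, decay_problem):
        rhs, exact, lam = decay_problem

        def f(t, x, u):
            return rhs(t, x)

        ts, xs, n_rhs = solve_adaptive(f, [1.0], 0.0, 1.0, 1e-6, 1e-9)
        comp = Component("c", f, [1.0], rel_tol=1e-6, abs_tol=1e-9)
        res = MultirateEngine([comp], EngineConfig(t_end=1.0)).run()
        assert res.status == "completed"
        np.testing.assert_array_equal(ts, res.times["c"])
        np.testing.assert_array_equal(xs, res.states["c"])

    def test_t_end_zero_returns_initial_state(self):
        comp = Component("c", lambda t, x, u: -x, [2.0])
        res = MultirateEngine([comp], EngineConfig(t_end=0.0)).run()
        assert res.times["c"].tolist() == [0.0]
        assert res.counters.accepted_macro == 0

    def test_decoupled_pair_matches_standalone_solves(self):
        # outputs unused by the partner: trajectories must match standalone runs
        def f1(t, x, u):
            return -2.0 * x

        def f2(t, x, u):
            return -40.0 * x + np.sin(10 * t)

        c1 = Component("s1", f1, [1.0], rel_tol=1e-6, abs_tol=1e-9)
        c2 = Component("s2", f2, [0.5], rel_tol=1e-6, abs_tol=1e-9)
        res = MultirateEngine([c1, c2], EngineConfig(t_end=1.0)).run()
        t1, x1, _ = solve_adaptive(f1, [1.0], 0.0, 1.0, 1e-6, 1e-9)
        t2, x2, _ = solve_adaptive(f2, [0.5], 0.0, 1.0, 1e-6, 1e-9)
        # same final state to well within the tolerance scale
        # agreement at the tolerance scale: the coupled error rule may choose
        # a different (valid) step sequence than the standalone controller
        assert res.state_at("s1", 1.0)[0] == pytest.approx(x1[-1, 0], abs=1e-5)
        assert res.state_at("s2", 1.0)[0] == pytest.approx(x2[-1, 0], abs=1e-5)


class TestMultirateRuns:
    @pytest.mark.parametrize("strategy", ["fast-first", "slow-first"])
    @pytest.mark.parametrize("communication", ["synchronous", "asynchronous"])
    def test_completes_and_gates_by_coupled_error(self, synthetic_smooth, strategy, communication):
        cfg = EngineConfig(t_end=0.3, strategy=strategy, communication=communication)
        res = MultirateEngine(synthetic_smooth.components(rel_tol=1e-5), cfg).run()
        assert res.status == "completed"
        violations = gating_violations(res.trace)
        assert violations == 0

    def test_accepted_steps_tile_the_interval(self, synthetic_smooth):
        cfg = EngineConfig(t_end=0.3)
        res = MultirateEngine(synthetic_smooth.components(rel_tol=1e-5), cfg).run()
        for cid in ("slow", "fast"):
            recs = sorted(
                (r for r in res.trace if r.component == cid and r.accepted and not r.discarded),
                key=lambda r: r.t_start,
            )
            for a, b in zip(recs, recs[1:]):
                assert b.t_start == pytest.approx(a.t_end, abs=1e-12)
            assert recs[0].t_start == 0.0
            assert recs[-1].t_end >= 0.3 - 1e-12

    def test_synchronous_grids_nested(self, synthetic_smooth):
        cfg = EngineConfig(t_end=0.2, communication="synchronous")
        res = MultirateEngine(synthetic_smooth.components(rel_tol=1e-5), cfg).run()
        slow_t = res.times["slow"]
        fast_t = set(np.round(res.times["fast"], 12))
        missing = [t for t in slow_t if np.round(t, 12) not in fast_t]
        assert not missing  # slower grid is a subset of the faster grid

    def test_macro_count_bounded_by_fast_micro_count(self, synthetic_smooth):
        cfg = EngineConfig(t_end=0.3)
        res = MultirateEngine(synthetic_smooth.components(rel_tol=1e-5), cfg).run()
        assert res.counters.accepted_macro <= res.counters.per_component["fast"]["accepted_micro"]

    def test_singlerate_identical_components_share_step_sequence(self):
        def f(t, x, u):
            return -3.0 * x + np.sin(5 * t)

        c1 = Component("a", f, [1.0], rel_tol=1e-6, abs_tol=1e-9)
        c2 = Component("b", f, [1.0], rel_tol=1e-6, abs_tol=1e-9)
        cfg = EngineConfig(t_end=0.5, mode="singlerate")
        res = MultirateEngine([c1, c2], cfg).run()
        np.testing.assert_array_equal(res.times["a"], res.times["b"])
        np.testing.assert_array_equal(res.states["a"], res.states["b"])

    def test_communication_count_independent_of_micro_steps(self, synthetic_smooth):
        # slow->fast communications per macro step do not grow when a tighter
        # tolerance multiplies the fast component's micro count
        counts = {}
        for tol in (1e-4, 1e-6):
            cfg = EngineConfig(t_end=0.3, strategy="slow-first")
            res = MultirateEngine(synthetic_smooth.components(rel_tol=tol), cfg).run()
            per_macro = (
                res.counters.communications[("slow", "fast")]
                / res.counters.accepted_macro
            )
            counts[tol] = per_macro
        assert counts[1e-4] == pytest.approx(counts[1e-6], rel=0.2)

    def test_h211b_filter_runs_and_gates(self, synthetic_smooth):
        cfg = EngineConfig(t_end=0.2, controller_filter="h211b")
        res = MultirateEngine(synthetic_smooth.components(rel_tol=1e-5), cfg).run()
        assert res.status == "completed"
        assert gating_violations(res.trace) == 0

    def test_multirate_slow_steps_fewer_than_singlerate(self, synthetic_smooth):
        slow_steps = {}
        for mode in ("multirate", "singlerate"):
            cfg = EngineConfig(t_end=0.3, mode=mode)
            res = MultirateEngine(synthetic_smooth.components(rel_tol=1e-6), cfg).run()
            slow_steps[mode] = res.counters.per_component["slow"]["accepted_micro"]
        assert slow_steps["multirate"] < slow_steps["singlerate"]


class TestRollbackAndAbort:
    def test_persistent_rejection_aborts_with_pristine_rollback(self):
        # an unresolvable error (tiny tolerance) forces max_rejections rollbacks;
        # the partial result must be flagged and histories restored bitwise
        def f_slow(t, x, u):
            return np.array([-x[0] + np.sin(50 * t)])

        def f_fast(t, x, u):
            return np.array([-200.0 * (x[0] - np.sin(5 * t))])

        slow = Component("slow", f_slow, [1.0], rel_tol=1e-15, abs_tol=1e-18)
        fast = Component("fast", f_fast, [0.0], rel_tol=1e-6, abs_tol=1e-9)
        cfg = EngineConfig(t_end=1.0, max_rejections=4)
        res = MultirateEngine([slow, fast], cfg).run()
        assert res.status == "aborted"
        assert "rejections" in res.message
        # the aborted step was rolled back: logs contain only pre-step entries
        # and the histories match them bitwise
        assert slow.solution_times == list(res.times["slow"])
        assert slow.history.times[-1] == res.times["slow"][-1]
        np.testing.assert_array_equal(
            slow.history.states[-1], res.states["slow"][-1]
        )
        np.testing.assert_array_equal(
            fast.history.states[-1], res.states["fast"][-1]
        )

    def test_component_snapshot_restore_bitwise(self):
        comp = Component("c", lambda t, x, u: -x, [1.0], rel_tol=1e-6, abs_tol=1e-9)
        comp.initialize(0.0)
        comp.h_pred = 0.1
        snap = comp.snapshot()
        before = (list(comp.history.times), [s.copy() for s in comp.history.states],
                  comp.h_pred, comp.controller.h_prev)
        comp.history.append(0.1, np.array([0.9]))
        comp.exchange.append(0.1, np.array([0.9]))
        comp.h_pred = 0.2
        comp.controller.h_prev = 0.1
        comp.solution_times.append(0.1)
        comp.solution_states.append(np.array([0.9]))
        comp.restore(snap)
        assert comp.history.times == before[0]
        for a, b in zip(comp.history.states, before[1]):
            np.testing.assert_array_equal(a, b)
        assert comp.h_pred == before[2]
        assert comp.controller.h_prev == before[3]
        assert len(comp.solution_times) == 1

    def test_rejected_fast_work_is_flagged_discarded(self, synthetic_smooth):
        cfg = EngineConfig(t_end=0.3)
        res = MultirateEngine(synthetic_smooth.components(rel_tol=1e-5), cfg).run()
        rejected = [r for r in res.trace if not r.accepted]
        if rejected:  # rejections occur on this problem at this tolerance
            assert any(r.discarded for r in res.trace)
        # counters monotone and consistent
        for cid, c in res.counters.per_component.items():
            assert c["discarded_micro"] <= c["accepted_micro"]
            assert c["rhs_evals"] >= c["jacobian_rhs_evals"]


class TestEngineConfigValidation:
    def test_bad_strategy(self):
        with pytest.raises(ValueError, match="strategy"):
            EngineConfig(strategy="fastest-first")

    def test_bad_mode(self):
        with pytest.raises(ValueError, match="mode"):
            EngineConfig(mode="dual")

    def test_bad_communication(self):
        with pytest.raises(ValueError, match="communication"):
            EngineConfig(communication="sometimes")

    def test_duplicate_ids_rejected(self):
        c1 = Component("x", lambda t, x, u: -x, [1.0])
        c2 = Component("x", lambda t, x, u: -x, [1.0])
        with pytest.raises(ValueError, match="duplicate"):
            MultirateEngine([c1, c2], EngineConfig())
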