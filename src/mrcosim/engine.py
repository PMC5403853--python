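"""Multirate Gauss-Seidel co-simulation engine.

The engine advances an ordered set of components — slowest to fastest, ordered
by their predicted step sizes — through a recursive SOLVE_INTERVAL procedure.
At each level the current (slowest remaining) component takes adaptive micro
steps across the interval handed down by its slower parent; for every micro
step the remaining faster subset is advanced across that step by a recursive
call.  Exchanged variables of partners that have already stepped over the
interval are obtained by quadratic interpolation of their published samples;
partners that have not yet stepped are extrapolated.  The two Gauss-Seidel
strategies differ only in the order within a micro step:

* fast-first: the faster subset is solved to the micro endpoint first (using
  extrapolated slow values), then the current component takes its corrector
  step with the fresh fast values;
* slow-first: the current component steps first (extrapolating its faster
  partners), then the faster subset is solved across the step, interpolating
  the now-known slow values.

With synchronous communication every component's last micro step inside an
interval is shrunk to land exactly on the interval endpoint, so slower grids
are subsets of faster ones.  With asynchronous communication faster
components may overshoot the endpoint (by at most one predicted step) and
values at the endpoint are interpolated; the overshooting step is kept for
the next interval.

Acceptance of a micro step is gated by the coupled error rule: the combined
error is the maximum of the component's own predictor-corrector error and the
largest accepted error of its next-faster neighbour over the overlapping
micro steps.  A rejection rolls back the component *and* every faster
component's micro steps inside the rejected interval, bitwise.

A singlerate mode forces one shared adaptive step for all components,
reproducing the classic Gauss-Seidel singlerate coupling as a reference
method, and a single-component run degenerates to a plain adaptive BDF2
solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .bdf2 import IntegratorError, bdf1_startup_step, bdf2_step
from .controller import (
    ControllerState,
    ErrorEstimate,
    accept,
    combine_with_faster,
    estimate_local_error,
    initial_step,
    predict_step,
)
from .history import (
    ComponentState,
    ExchangeRecord,
    classify_query,
    poly2_eval,
)

__all__ = [
    "Component",
    "EngineConfig",
    "StepCounters",
    "StepRecord",
    "SimulationResult",
    "MultirateEngine",
    "EngineError",
    "order_components",
    "exchange_at",
    "gating_violations",
    "align_macro_end",
    "solve_adaptive",
    "run",
]

FAST_FIRST = "fast-first"
SLOW_FIRST = "slow-first"
SYNCHRONOUS = "synchronous"
ASYNCHRONOUS = "asynchronous"
MULTIRATE = "multirate"
SINGLERATE = "singlerate"


class EngineError(RuntimeError):
    """Unrecoverable engine failure (persistent rejections, invariant breach)."""


def _teps(t: float) -> float:
    """Absolute time comparison slack at time magnitude ``t``."""
    return 1e-12 * max(1.0, abs(t))


# --------------------------------------------------------------------------
# components


class Component:
    """One co-simulated subsystem.

    Wraps the right-hand side ``f(t, x, u)`` (``u`` maps partner ids to their
    exchanged vectors at the evaluation time), the output transformation
    ``g(x)`` producing the exchanged vector, per-component tolerances, and the
    mutable per-run state: solution history, published exchange samples,
    predicted step, controller memory and the full accepted-solution log.
    """

    def __init__(
        self,
        id: str,
        rhs: Callable,
        x0,
        output: Callable | None = None,
        rel_tol: float = 1e-6,
        abs_tol=1e-9,
        controller: ControllerState | None = None,
        retention: int = 8,
        h_max: float = math.inf,
    ):
        self.id = str(id)
        self.h_max = float(h_max)
        if not self.h_max > 0:
            raise ValueError(f"h_max must be positive, got {h_max}")
        self.rhs = rhs
        self.x0 = np.atleast_1d(np.asarray(x0, dtype=float))
        self.output = output if output is not None else (lambda x: x)
        self.rel_tol = float(rel_tol)
        if not self.rel_tol >= 0:
            raise ValueError(f"relTOL must be >= 0, got {rel_tol}")
        self.abs_tol = np.broadcast_to(
            np.asarray(abs_tol, dtype=float), self.x0.shape
        ).copy()
        if np.any(self.abs_tol <= 0):
            raise ValueError(f"absTOL must be positive for component {id!r}")
        self.controller = controller if controller is not None else ControllerState()
        self.retention = retention
        self.reset()

    def reset(self, t0: float = 0.0) -> None:
        self.history = ComponentState(retention=self.retention)
        self.exchange = ExchangeRecord(self.id, retention=self.retention)
        self.h_pred: float = math.nan
        self.last_estimate: ErrorEstimate | None = None
        self.solution_times: list[float] = []
        self.solution_states: list[np.ndarray] = []
        self.recent_records: list["StepRecord"] = []
        self._t0 = t0

    @property
    def time(self) -> float:
        return self.history.last_time

    @property
    def state(self) -> np.ndarray:
        return self.history.last_state

    def initialize(self, t0: float) -> None:
        self.reset(t0)
        self.history.append(t0, self.x0)
        self.exchange.append(t0, self.output(self.x0))
        self.solution_times.append(t0)
        self.solution_states.append(self.x0.copy())

    def snapshot(self) -> tuple:
        return (
            self.history.snapshot(),
            self.exchange.snapshot(),
            self.h_pred,
            self.controller.copy(),
            len(self.solution_times),
            len(self.recent_records),
        )

    def restore(self, snap: tuple) -> None:
        hist, exch, h_pred, ctrl, n_sol, n_rec = snap
        self.history.restore(hist)
        self.exchange.restore(exch)
        self.h_pred = h_pred
        self.controller = ctrl
        del self.solution_times[n_sol:]
        del self.solution_states[n_sol:]
        del self.recent_records[n_rec:]


# --------------------------------------------------------------------------
# configuration, counters, trace


@dataclass
class EngineConfig:
    """Run configuration: strategy, communication mode, rate mode, end time."""

    t_end: float = 1.0
    strategy: str = FAST_FIRST
    communication: str = ASYNCHRONOUS
    mode: str = MULTIRATE
    t_start: float = 0.0
    reorder: bool = True
    max_rejections: int = 20
    controller_filter: str = "elementary"
    record_trace: bool = True

    def __post_init__(self):
        if self.strategy not in (FAST_FIRST, SLOW_FIRST):
            raise ValueError(
                f"strategy must be {FAST_FIRST!r} or {SLOW_FIRST!r}, "
                f"got {self.strategy!r}"
            )
        if self.communication not in (SYNCHRONOUS, ASYNCHRONOUS):
            raise ValueError(
                f"communication must be {SYNCHRONOUS!r} or {ASYNCHRONOUS!r}, "
                f"got {self.communication!r}"
            )
        if self.mode not in (MULTIRATE, SINGLERATE):
            raise ValueError(
                f"mode must be {MULTIRATE!r} or {SINGLERATE!r}, got {self.mode!r}"
            )
        if self.controller_filter not in ("elementary", "h211b"):
            raise ValueError(
                f"controller_filter must be 'elementary' or 'h211b', "
                f"got {self.controller_filter!r}"
            )
        if not self.t_end >= self.t_start:
            raise ValueError("t_end must be >= t_start")


@dataclass
class StepRecord:
    """One accepted or rejected step attempt of one component."""

    component: str
    t_start: float
    t_end: float
    h: float
    local_error: float
    combined_error: float
    accepted: bool
    formula: str  # "bdf1" or "bdf2"
    n_rhs: int
    discarded: bool = False
    queries: list = field(default_factory=list)  # (source, t, classification)
    #: ids of the faster subset advanced inside this step (slowest first)
    faster_ids: tuple = ()


def _new_comp_counter() -> dict:
    return {
        "rhs_evals": 0,
        "jacobian_rhs_evals": 0,
        "accepted_micro": 0,
        "discarded_micro": 0,
        "rejected": 0,
    }


@dataclass
class StepCounters:
    """Work and step bookkeeping, per component and global.

    All counters are monotone during a run; micro steps that are later
    discarded by a slower component's rejection stay in ``accepted_micro`` and
    are additionally counted in ``discarded_micro``.
    """

    per_component: dict = field(default_factory=dict)
    accepted_macro: int = 0
    order_switches: int = 0
    communications: dict = field(default_factory=dict)

    def component(self, cid: str) -> dict:
        return self.per_component.setdefault(cid, _new_comp_counter())

    def add_rhs(self, cid: str, n: int, n_jac: int = 0) -> None:
        c = self.component(cid)
        c["rhs_evals"] += n
        c["jacobian_rhs_evals"] += n_jac

    def communicate(self, source: str, target: str) -> None:
        key = (source, target)
        self.communications[key] = self.communications.get(key, 0) + 1

    @property
    def total_rhs_evals(self) -> int:
        return sum(c["rhs_evals"] for c in self.per_component.values())

    @property
    def total_rhs_evals_excluding_jacobian(self) -> int:
        return sum(
            c["rhs_evals"] - c["jacobian_rhs_evals"]
            for c in self.per_component.values()
        )

    @property
    def total_accepted_micro(self) -> int:
        return sum(c["accepted_micro"] for c in self.per_component.values())

    @property
    def total_rejected(self) -> int:
        return sum(c["rejected"] for c in self.per_component.values())


@dataclass
class SimulationResult:
    """Accepted trajectories, counters and the per-step trace of one run."""

    times: dict
    states: dict
    counters: StepCounters
    trace: list
    config: EngineConfig
    status: str = "completed"
    message: str = ""

    def state_at(self, cid: str, t: float) -> np.ndarray:
        """Quadratic interpolation of the stored solution at time ``t``."""
        times = self.times[cid]
        states = self.states[cid]
        idx = int(np.searchsorted(times, t))
        lo = max(0, min(idx - 1, len(times) - 3))
        samples = [(times[i], states[i]) for i in range(lo, min(lo + 3, len(times)))]
        return poly2_eval(samples, t)

    def sample(self, cid: str, grid) -> np.ndarray:
        """Trajectory of one component resampled on ``grid`` (rows = times)."""
        grid = np.atleast_1d(np.asarray(grid, dtype=float))
        return np.vstack([self.state_at(cid, t) for t in grid])


# --------------------------------------------------------------------------
# free functions of the engine interface


def order_components(
    components: Sequence[Component],
    previous_order: Sequence[str] | None = None,
) -> tuple[list[Component], bool]:
    """Sort components slowest to fastest by predicted step (stable).

    Returns the ordered list and whether the order changed relative to
    ``previous_order`` (the switch event the counters record).
    """
    for c in components:
        if not (c.h_pred > 0):
            raise EngineError(f"component {c.id!r} has no predicted step")
    ordered = sorted(components, key=lambda c: -c.h_pred)  # stable
    ids = [c.id for c in ordered]
    switched = previous_order is not None and list(previous_order) != ids
    return ordered, switched


def exchange_at(
    target: Component,
    source: Component,
    t: float,
    role: str | None = None,
) -> tuple[np.ndarray, str]:
    """Exchanged vector of ``source`` approximated at time ``t`` for ``target``.

    Uses the newest (at most three) published samples of the source's output;
    whether this is an interpolation or an extrapolation follows from the
    sample span and is returned for diagnostics.  ``role`` is an optional
    caller annotation ("already-solved" / "not-yet-solved") and does not
    change the numerics.
    """
    if len(source.exchange) == 0:
        raise EngineError(
            f"component {source.id!r} has no exchange samples for {target.id!r}"
        )
    samples = source.exchange.recent(3)
    value = poly2_eval(samples, t)
    classification = classify_query(samples, t)
    return value, classification


def align_macro_end(fast: Component, t_end_macro: float, communication: str):
    """Exchanged value of a faster component exactly at a macro endpoint.

    Synchronous mode requires the component to have landed on the endpoint
    (its stored value is returned); asynchronous mode interpolates between the
    bracketing micro points of the (possibly overshooting) grid.
    """
    t_last = fast.exchange.times[-1]
    if communication == SYNCHRONOUS:
        if abs(t_last - t_end_macro) > _teps(t_end_macro):
            raise EngineError(
                f"synchronous mode: component {fast.id!r} at t={t_last} "
                f"did not land on macro endpoint {t_end_macro}"
            )
        return fast.exchange.values[-1].copy()
    if t_last < t_end_macro - _teps(t_end_macro):
        raise EngineError(
            f"component {fast.id!r} at t={t_last} has not reached "
            f"macro endpoint {t_end_macro}"
        )
    return fast.exchange.eval_at(t_end_macro)


# --------------------------------------------------------------------------
# the engine


class MultirateEngine:
    def __init__(self, components: Sequence[Component], config: EngineConfig):
        if len(components) == 0:
            raise ValueError("need at least one component")
        ids = [c.id for c in components]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate component ids: {ids}")
        self.components = list(components)
        self.config = config
        self.counters = StepCounters()
        self.trace: list[StepRecord] = []
        self._prev_order: list[str] | None = None
        self._last_queries: list = []

    # -- setup ------------------------------------------------------------

    def _initialize(self) -> None:
        cfg = self.config
        t0 = cfg.t_start
        for c in self.components:
            c.controller.filter = cfg.controller_filter
            c.initialize(t0)
        for c in self.components:
            u = self._gather_exchanged(c, t0, log=False)
            h0, n = initial_step(
                c.rhs, t0, c.x0, u, c.rel_tol, c.abs_tol, cfg.t_end - t0
            )
            self.counters.add_rhs(c.id, n)
            c.h_pred = min(h0, c.h_max)
        if cfg.mode == SINGLERATE:
            h_shared = min(c.h_pred for c in self.components)
            for c in self.components:
                c.h_pred = h_shared
            self._shared_controller = ControllerState(filter=cfg.controller_filter)

    # -- exchanged variables ----------------------------------------------

    def _gather_exchanged(self, target: Component, t: float, log: bool = True):
        u = {}
        queries = []
        for source in self.components:
            if source is target:
                continue
            value, classification = exchange_at(target, source, t)
            u[source.id] = value
            if log:
                queries.append((source.id, t, classification))
        self._last_queries = queries
        return u

    # -- one component micro step -----------------------------------------

    def _step_component(self, comp: Component, h: float):
        """Tentatively advance ``comp`` by ``h``: predictor, implicit corrector,
        local error estimate, commit to history/exchange/solution log."""
        t_now = comp.time
        t_new = t_now + h
        u = self._gather_exchanged(comp, t_new)
        x_pred = poly2_eval(comp.history.recent(3), t_new)
        if len(comp.history) < 2:
            formula = "bdf1"
            x_new, report = bdf1_startup_step(
                comp.state,
                t_now,
                h,
                comp.rhs,
                u,
                x_predict=x_pred,
                rel_tol=comp.rel_tol,
                abs_tol=comp.abs_tol,
            )
        else:
            formula = "bdf2"
            x_new, report = bdf2_step(
                comp.history,
                h,
                comp.rhs,
                u,
                x_predict=x_pred,
                rel_tol=comp.rel_tol,
                abs_tol=comp.abs_tol,
            )
        self.counters.add_rhs(
            comp.id, report.rhs_evaluations, report.jacobian_evaluations
        )
        if not report.converged:
            raise IntegratorError(
                f"implicit solve for {comp.id!r} did not converge at t={t_new}"
            )
        est = estimate_local_error(x_new, x_pred, comp.rel_tol, comp.abs_tol)
        comp.history.append(t_new, x_new)
        comp.exchange.append(t_new, comp.output(x_new))
        comp.solution_times.append(t_new)
        comp.solution_states.append(x_new.copy())
        return est, report, formula

    # -- coupled error bookkeeping ----------------------------------------

    def _faster_errors(self, faster: Component, t_lo: float, t_hi: float):
        """Accepted combined errors of the next-faster component over micro
        steps intersecting (t_lo, t_hi) — including, in asynchronous mode, the
        step overshooting the interval end."""
        errors = []
        eps = _teps(t_hi)
        for rec in reversed(faster.recent_records):
            if rec.t_end <= t_lo + eps:
                break
            if rec.t_start < t_hi - eps:
                errors.append(rec.combined_error)
        return errors

    # -- recursive interval solve ------------------------------------------

    def _solve_interval(
        self,
        t0: float,
        t1: float,
        subset: list[Component],
        outermost_h: float | None = None,
    ) -> None:
        cfg = self.config
        comp = subset[0]
        faster = subset[1:]
        sync = cfg.communication == SYNCHRONOUS

        while comp.time < t1 - _teps(t1):
            t_now = comp.time
            if outermost_h is not None:
                h = outermost_h
            else:
                h = comp.h_pred
                # synchronous: shrink the last micro step to land exactly on
                # t1.  asynchronous: the innermost (fastest) component may
                # overshoot t1 by at most one predicted step; components that
                # still carry a faster subset land exactly so the recursion
                # below them stays well posed.
                if sync or faster:
                    if t_now + h >= t1 - _teps(t1):
                        h = t1 - t_now

            rejections = 0
            while True:
                snaps = [(c, c.snapshot()) for c in subset]
                trace_mark = len(self.trace)
                t_new = t_now + h
                failed = None
                est = None
                formula = "bdf2"
                n_rhs_before = self.counters.component(comp.id)["rhs_evals"]
                try:
                    if cfg.strategy == FAST_FIRST and faster:
                        self._solve_interval(t_now, t_new, faster)
                    est, report, formula = self._step_component(comp, h)
                    if cfg.strategy == SLOW_FIRST and faster:
                        self._solve_interval(t_now, t_new, faster)
                except IntegratorError as exc:
                    failed = exc

                if failed is None:
                    f_errs = (
                        self._faster_errors(faster[0], t_now, t_new)
                        if faster
                        else []
                    )
                    combined = combine_with_faster(est, f_errs)
                    ok = accept(combined)
                else:
                    combined = math.inf
                    ok = False

                n_rhs_step = (
                    self.counters.component(comp.id)["rhs_evals"] - n_rhs_before
                )
                if ok:
                    comp.h_pred = min(
                        predict_step(comp.controller, combined, h), comp.h_max
                    )
                    comp.last_estimate = est
                    record = StepRecord(
                        component=comp.id,
                        t_start=t_now,
                        t_end=t_new,
                        h=h,
                        local_error=est.local_scalar,
                        combined_error=combined,
                        accepted=True,
                        formula=formula,
                        n_rhs=n_rhs_step,
                        queries=list(self._last_queries),
                        faster_ids=tuple(c.id for c in faster),
                    )
                    if cfg.record_trace:
                        self.trace.append(record)
                    comp.recent_records.append(record)
                    if len(comp.recent_records) > 1000:
                        del comp.recent_records[:500]
                    cc = self.counters.component(comp.id)
                    cc["accepted_micro"] += 1
                    for fc in faster:
                        self.counters.communicate(comp.id, fc.id)
                        self.counters.communicate(fc.id, comp.id)
                    break

                # rejection: roll everything in the subset back, bitwise,
                # and flag the micro steps computed inside the interval.
                for c, snap in snaps:
                    n_rec_before = snap[5]
                    for rec in c.recent_records[n_rec_before:]:
                        rec.discarded = True
                        self.counters.component(c.id)["discarded_micro"] += 1
                    c.restore(snap)
                for rec in self.trace[trace_mark:]:
                    rec.discarded = True
                self.counters.component(comp.id)["rejected"] += 1
                if cfg.record_trace:
                    self.trace.append(
                        StepRecord(
                            component=comp.id,
                            t_start=t_now,
                            t_end=t_new,
                            h=h,
                            local_error=(est.local_scalar if est else math.inf),
                            combined_error=combined,
                            accepted=False,
                            formula=formula,
                            n_rhs=n_rhs_step,
                        )
                    )
                rejections += 1
                if rejections > cfg.max_rejections:
                    raise EngineError(
                        f"component {comp.id!r}: {rejections} consecutive "
                        f"rejections at t={t_now} (h={h}, error={combined})"
                    )
                if failed is not None:
                    h = 0.5 * h
                else:
                    h = predict_step(
                        comp.controller, combined, h, rejected=True
                    )

            if outermost_h is not None:
                # the outermost interval ends at the slowest component's
                # accepted step; do not try to cover the originally
                # predicted span after a rejection shrank the step.
                break

    # -- singlerate sweep ---------------------------------------------------

    def _run_singlerate(self) -> None:
        cfg = self.config
        t_end = cfg.t_end
        sweep = sorted(
            self.components,
            key=lambda c: -c.h_pred,
        )
        if cfg.strategy == FAST_FIRST:
            sweep = list(reversed(sweep))
        t = self.components[0].time
        h = self.components[0].h_pred
        while t < t_end - _teps(t_end):
            h = min(h, t_end - t)
            rejections = 0
            while True:
                snaps = [(c, c.snapshot()) for c in self.components]
                trace_mark = len(self.trace)
                failed = None
                estimates = {}
                try:
                    for c in sweep:
                        est, report, formula = self._step_component(c, h)
                        estimates[c.id] = (est, formula)
                except IntegratorError as exc:
                    failed = exc
                if failed is None:
                    combined = max(e.local_scalar for e, _ in estimates.values())
                    ok = accept(combined)
                else:
                    combined = math.inf
                    ok = False
                if ok:
                    for c in sweep:
                        est, formula = estimates[c.id]
                        est.faster_max = combined if est.local_scalar < combined else 0.0
                        record = StepRecord(
                            component=c.id,
                            t_start=t,
                            t_end=t + h,
                            h=h,
                            local_error=est.local_scalar,
                            combined_error=combined,
                            accepted=True,
                            formula=formula,
                            n_rhs=0,
                        )
                        if cfg.record_trace:
                            self.trace.append(record)
                        c.recent_records.append(record)
                        self.counters.component(c.id)["accepted_micro"] += 1
                    for a in self.components:
                        for b in self.components:
                            if a is not b:
                                self.counters.communicate(a.id, b.id)
                    self.counters.accepted_macro += 1
                    t = t + h
                    h_next = predict_step(self._shared_controller, combined, h)
                    h_next = min(h_next, min(c.h_max for c in self.components))
                    for c in self.components:
                        c.h_pred = h_next
                    h = h_next
                    break
                for c, snap in snaps:
                    c.restore(snap)
                for rec in self.trace[trace_mark:]:
                    rec.discarded = True
                for c in sweep:
                    self.counters.component(c.id)["rejected"] += 1
                rejections += 1
                if rejections > cfg.max_rejections:
                    raise EngineError(
                        f"singlerate: {rejections} consecutive rejections "
                        f"at t={t} (h={h})"
                    )
                if failed is not None:
                    h = 0.5 * h
                else:
                    h = predict_step(
                        self._shared_controller, combined, h, rejected=True
                    )

    # -- outer loop ---------------------------------------------------------

    def run(self) -> SimulationResult:
        cfg = self.config
        self.counters = StepCounters()
        self.trace = []
        self._prev_order = None
        self._initialize()
        status, message = "completed", ""
        try:
            if cfg.mode == SINGLERATE:
                self._run_singlerate()
            else:
                t_end = cfg.t_end
                while True:
                    if min(c.time for c in self.components) >= t_end - _teps(
                        t_end
                    ):
                        break
                    if cfg.reorder:
                        ordered, switched = order_components(
                            self.components, self._prev_order
                        )
                        if switched:
                            self.counters.order_switches += 1
                        self._prev_order = [c.id for c in ordered]
                    else:
                        ordered = list(self.components)
                    head = ordered[0]
                    if head.time >= t_end - _teps(t_end):
                        # the head overshot t_end on a previous (faster) turn;
                        # bring the lagging subset up to t_end and finish.
                        lagging = [
                            c for c in ordered[1:] if c.time < t_end - _teps(t_end)
                        ]
                        self._solve_interval(
                            min(c.time for c in lagging), t_end, lagging
                        )
                        self.counters.accepted_macro += 1
                        continue
                    H = min(head.h_pred, t_end - head.time)
                    self._solve_interval(
                        head.time, head.time + H, ordered, outermost_h=H
                    )
                    self.counters.accepted_macro += 1
        except EngineError as exc:
            status, message = "aborted", str(exc)

        times = {
            c.id: np.asarray(c.solution_times, dtype=float)
            for c in self.components
        }
        states = {
            c.id: np.vstack(c.solution_states) for c in self.components
        }
        return SimulationResult(
            times=times,
            states=states,
            counters=self.counters,
            trace=self.trace,
            config=cfg,
            status=status,
            message=message,
        )


def run(
    config: EngineConfig,
    components: Sequence[Component],
    protocol: Callable | None = None,
) -> SimulationResult:
    """Convenience wrapper: build the engine and run it.

    ``protocol`` (an injected-current or stimulus schedule) is owned by the
    model right-hand sides; it is accepted here so callers can thread it
    through run manifests, but the engine itself never evaluates it.
    """
    engine = MultirateEngine(components, config)
    result = engine.run()
    return result


def gating_violations(trace, tol: float = 1e-12) -> int:
    """Check the coupled error rule on a recorded trace.

    For every accepted, non-discarded step of a component that carried a
    faster subset, the combined error must be <= 1 and at least the largest
    accepted error of the next-faster component over the overlapping micro
    steps recorded up to that point.  Returns the number of violations (0 on
    a correct trace).
    """
    violations = 0
    seen: dict = {}
    for rec in trace:
        if not rec.accepted or rec.discarded:
            continue
        if rec.combined_error > 1.0 + tol:
            violations += 1
        if rec.faster_ids:
            nxt = rec.faster_ids[0]
            eps = _teps(rec.t_end)
            overlapping = [
                f.combined_error
                for f in seen.get(nxt, [])
                if f.t_end > rec.t_start + eps and f.t_start < rec.t_end - eps
            ]
            if overlapping and rec.combined_error < max(overlapping) - tol:
                violations += 1
        seen.setdefault(rec.component, []).append(rec)
    return violations


# --------------------------------------------------------------------------
# standalone adaptive BDF2 (the degenerate-recursion oracle)


def solve_adaptive(
    rhs: Callable,
    x0,
    t0: float,
    t_end: float,
    rel_tol: float = 1e-6,
    abs_tol=1e-9,
    controller: ControllerState | None = None,
    max_rejections: int = 20,
    retention: int = 8,
):
    """Plain adaptive BDF2 solve of a single uncoupled ODE system.

    Implements exactly the per-component stepping sequence of the engine —
    initial-step heuristic, quadratic predictor, BDF1 startup then BDF2,
    predictor-corrector error, elementary controller — without any coupling
    machinery.  A single-component engine run reproduces this trajectory
    bitwise; the function exists as the independent reference for that check
    and as a generally useful solver for uncoupled problems.

    Returns ``(times, states, n_rhs_evals)``.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    ctrl = controller if controller is not None else ControllerState()
    history = ComponentState(retention=retention)
    history.append(t0, x0)
    sol_t = [t0]
    sol_x = [x0.copy()]
    n_rhs = 0

    u: dict = {}
    h_pred, n = initial_step(rhs, t0, x0, u, rel_tol, abs_tol, t_end - t0)
    n_rhs += n

    t = t0
    while t < t_end - _teps(t_end):
        h = min(h_pred, t_end - t)
        rejections = 0
        while True:
            t_new = t + h
            x_pred = poly2_eval(history.recent(3), t_new)
            failed = False
            try:
                if len(history) < 2:
                    x_new, report = bdf1_startup_step(
                        history.last_state,
                        t,
                        h,
                        rhs,
                        u,
                        x_predict=x_pred,
                        rel_tol=rel_tol,
                        abs_tol=abs_tol,
                    )
                else:
                    x_new, report = bdf2_step(
                        history,
                        h,
                        rhs,
                        u,
                        x_predict=x_pred,
                        rel_tol=rel_tol,
                        abs_tol=abs_tol,
                    )
                n_rhs += report.rhs_evaluations
                if not report.converged:
                    raise IntegratorError("no convergence")
            except IntegratorError:
                failed = True
            if not failed:
                est = estimate_local_error(x_new, x_pred, rel_tol, abs_tol)
                combined = combine_with_faster(est, [])
                if accept(combined):
                    h_pred = predict_step(ctrl, combined, h)
                    history.append(t_new, x_new)
                    sol_t.append(t_new)
                    sol_x.append(x_new.copy())
                    t = t_new
                    break
            rejections += 1
            if rejections > max_rejections:
                raise EngineError(
                    f"standalone solver: {rejections} consecutive rejections "
                    f"at t={t} (h={h})"
                )
            if failed:
                h = 0.5 * h
            else:
                h = predict_step(ctrl, combined, h, rejected=True)
    return np.asarray(sol_t), np.vstack(sol_x), n_rhs
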