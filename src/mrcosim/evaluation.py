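"""Accuracy and cost evaluation of coupled runs.

Accuracy is measured as the relative error (in percent) of a chosen
observable at a fixed evaluation time against a reference trajectory obtained
by solving both components as one monolithic system with a stiff variable-step
solver at tolerance 1e-12.  Cost is the total number of right-hand-side
evaluations ("ODE calls"), counted inclusive of the evaluations spent on
finite-difference Jacobians (an exclusive count is reported alongside).
Convergence order is the least-squares slope of log(error) versus log(cost)
over a tolerance sweep, reported as a positive decline order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .engine import EngineConfig, MultirateEngine

__all__ = [
    "ReferenceSolution",
    "AccuracyCostPoint",
    "relative_error",
    "compute_reference",
    "convergence_order",
    "run_sweep",
]

REFERENCE_TOL = 1e-12


class EvaluationError(ValueError):
    pass


def relative_error(x_ref: float, x: float) -> float:
    """Relative error |x_ref - x| / |x_ref| in percent.

    Deliberately asymmetric (normalized by the reference, not a symmetric
    difference); the reference must be nonzero.
    """
    if x_ref == 0:
        raise EvaluationError("reference value is zero; pick a nonzero observable")
    return abs(x_ref - x) / abs(x_ref) * 100.0


@dataclass
class ReferenceSolution:
    """Dense monolithic reference trajectory with an interpolation accessor."""

    tolerance: float
    t_span: tuple
    _sol: object = None
    n_rhs: int = 0

    def __call__(self, t):
        y = self._sol(t)
        return np.asarray(y)

    @property
    def t_end_state(self):
        return self(self.t_span[1])


def compute_reference(
    problem,
    t_end: float,
    tol: float = REFERENCE_TOL,
    method: str = "BDF",
) -> ReferenceSolution:
    """Solve the monolithic coupled system stiffly at tolerance ``tol``.

    ``problem`` must expose ``monolithic_rhs(t, x)`` and ``x0_monolithic()``.
    """
    x0 = problem.x0_monolithic()
    n_calls = 0

    def rhs(t, x):
        nonlocal n_calls
        n_calls += 1
        return problem.monolithic_rhs(t, x)

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        x0,
        method=method,
        rtol=max(tol, 1e-13),
        atol=tol,
        dense_output=True,
    )
    if not sol.success:
        raise EvaluationError(f"reference solve failed: {sol.message}")
    return ReferenceSolution(
        tolerance=tol, t_span=(0.0, t_end), _sol=sol.sol, n_rhs=n_calls
    )


@dataclass
class AccuracyCostPoint:
    """One datapoint of an accuracy-versus-cost sweep."""

    rel_tol: float
    errors: dict  # observable name -> relative error (%)
    ode_calls: int
    ode_calls_excluding_jacobian: int
    micro_steps: int
    macro_steps: int
    rejected_steps: int
    order_switches: int
    status: str = "completed"


def convergence_order(points) -> float:
    """Least-squares slope of log(error) vs log(cost), as a positive order.

    ``points`` is either a list of :class:`AccuracyCostPoint` (the first
    observable of each is used) or a pair ``(errors, costs)``.
    """
    if isinstance(points, tuple) and len(points) == 2:
        errors, costs = (np.asarray(v, dtype=float) for v in points)
    else:
        pts = list(points)
        if pts and isinstance(pts[0], AccuracyCostPoint):
            key = next(iter(pts[0].errors))
            errors = np.array([p.errors[key] for p in pts], dtype=float)
            costs = np.array([p.ode_calls for p in pts], dtype=float)
        else:
            raise EvaluationError("pass AccuracyCostPoints or (errors, costs)")
    if errors.size < 2:
        raise EvaluationError("need at least 2 points for a slope")
    if np.any(errors <= 0) or np.any(costs <= 0):
        raise EvaluationError("errors and costs must be positive for a log fit")
    log_c = np.log10(costs)
    log_e = np.log10(errors)
    if np.ptp(log_c) < 1e-12:
        raise EvaluationError("degenerate cost spread")
    slope = np.polyfit(log_c, log_e, 1)[0]
    return -slope


def run_sweep(
    problem,
    tolerances,
    config: EngineConfig,
    observables: dict | None = None,
    t_eval: float | None = None,
    reference: ReferenceSolution | None = None,
) -> tuple[list[AccuracyCostPoint], pd.DataFrame]:
    """One engine run per tolerance; errors at ``t_eval`` against the reference.

    ``problem`` must provide ``components(rel_tol)``, ``monolithic_rhs``,
    ``x0_monolithic`` and (optionally) ``observables`` /
    ``observable_monolithic_index``.  Individual run failures are recorded and
    the sweep continues.  Returns the points and a tidy DataFrame.
    """
    t_eval = config.t_end if t_eval is None else t_eval
    if observables is None:
        observables = getattr(problem, "observables")
    if reference is None:
        reference = compute_reference(problem, max(t_eval, config.t_end))
    x_ref = reference(t_eval)

    points = []
    for tol in tolerances:
        comps = problem.components(rel_tol=tol)
        engine = MultirateEngine(comps, config)
        result = engine.run()
        errors = {}
        if result.status == "completed":
            for name, (cid, idx) in observables.items():
                ref_val = x_ref[problem.observable_monolithic_index(name)]
                val = result.state_at(cid, t_eval)[idx]
                errors[name] = relative_error(ref_val, val)
        counters = result.counters
        micro = counters.total_accepted_micro
        points.append(
            AccuracyCostPoint(
                rel_tol=tol,
                errors=errors,
                ode_calls=counters.total_rhs_evals,
                ode_calls_excluding_jacobian=counters.total_rhs_evals_excluding_jacobian,
                micro_steps=micro,
                macro_steps=counters.accepted_macro,
                rejected_steps=counters.total_rejected,
                order_switches=counters.order_switches,
                status=result.status,
            )
        )

    rows = []
    for p in points:
        row = {
            "relTol": p.rel_tol,
            "micros": p.micro_steps,
            "macros": p.macro_steps,
            "rejected": p.rejected_steps,
            "ode_calls": p.ode_calls,
            "ode_calls_excl_jac": p.ode_calls_excluding_jacobian,
            "switches": p.order_switches,
            "status": p.status,
        }
        for name, err in p.errors.items():
            row[f"e_{name}"] = err
        rows.append(row)
    return points, pd.DataFrame(rows)
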