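"""Local error estimation, the coupled error rule, and step-size prediction.

Each component estimates its local discretization error with a
predictor-corrector pair: the corrector is the implicit BDF2 solution, the
predictor the second-order polynomial extrapolation of the component's own
history.  The normalized, component-wise error of component r at t_{n+1} is

    eps_{r,i} = |x_{r,i} - xhat_{r,i}| / (relTOL_r |x_{r,i}| + absTOL_{r,i})

and the scalar local error is the maximum over i.  The *coupled* error of a
slower component is the maximum of its own local error and the largest
accepted error of the next-faster component over the overlapping micro steps;
this single rule is what lets every component run its own step-size controller
without the slow component silently accepting an interval the fast component
could not resolve.

A normalized error <= 1 is accepted.  The next step is predicted by the
elementary controller

    h_next = h * clamp(safety * err^(-1/(p+1)), facmin, facmax),   p = 2,

optionally replaced by an H211b-style digital filter for smoother step
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

__all__ = [
    "ErrorEstimate",
    "ControllerState",
    "estimate_local_error",
    "combine_with_faster",
    "accept",
    "predict_step",
    "initial_step",
]


@dataclass
class ErrorEstimate:
    """Normalized local discretization error of one step of one component."""

    local_scalar: float
    componentwise: np.ndarray
    faster_max: float = 0.0

    @property
    def combined(self) -> float:
        return max(self.local_scalar, self.faster_max)


@dataclass
class ControllerState:
    """Per-component step-size controller memory and limits.

    The exponent 1/3 = 1/(order+1) matches the second-order method.  The
    clamp [facmin, facmax] keeps consecutive accepted step ratios bounded so
    the non-uniform BDF2 coefficients stay well conditioned.
    """

    safety: float = 0.9
    facmin: float = 0.2
    facmax: float = 2.0
    order_exponent: float = 1.0 / 3.0
    filter: str = "elementary"  # or "h211b"
    h_prev: float | None = None
    err_prev: float | None = None

    def __post_init__(self):
        if not (0.0 < self.facmin < 1.0 < self.facmax):
            raise ValueError(
                f"need 0 < facmin < 1 < facmax, got [{self.facmin}, {self.facmax}]"
            )
        if not (0.0 < self.safety <= 1.0):
            raise ValueError(f"safety must be in (0, 1], got {self.safety}")
        if self.filter not in ("elementary", "h211b"):
            raise ValueError(f"unknown controller filter {self.filter!r}")

    def copy(self) -> "ControllerState":
        return replace(self)


def estimate_local_error(
    x_corrected: np.ndarray,
    x_predicted: np.ndarray,
    rel_tol: float,
    abs_tol,
) -> ErrorEstimate:
    """Normalized predictor-corrector error, component-wise and scalar."""
    x = np.atleast_1d(np.asarray(x_corrected, dtype=float))
    xhat = np.atleast_1d(np.asarray(x_predicted, dtype=float))
    if x.shape != xhat.shape:
        raise ValueError(
            f"dimension mismatch: corrector {x.shape} vs predictor {xhat.shape}"
        )
    abs_tol = np.broadcast_to(np.asarray(abs_tol, dtype=float), x.shape)
    if not rel_tol >= 0 or np.any(abs_tol <= 0):
        raise ValueError("tolerances must be positive")
    componentwise = np.abs(x - xhat) / (rel_tol * np.abs(x) + abs_tol)
    return ErrorEstimate(
        local_scalar=float(np.max(componentwise)), componentwise=componentwise
    )


def combine_with_faster(
    local: ErrorEstimate, faster_errors: Iterable[float]
) -> float:
    """Coupled error: max of the local error and the faster components' errors.

    ``faster_errors`` are the accepted micro-step errors of the next-faster
    component over the (possibly overlapping) current interval; an empty
    collection — the fastest component — leaves the local error unchanged.
    The estimate is updated in place and the combined scalar returned.
    """
    faster_errors = list(faster_errors)
    local.faster_max = max(faster_errors) if faster_errors else 0.0
    return local.combined


def accept(combined: float) -> bool:
    """A step is accepted iff its combined normalized error is <= 1."""
    if combined < 0:
        raise ValueError(f"normalized error must be >= 0, got {combined}")
    return combined <= 1.0


def predict_step(
    state: ControllerState,
    combined: float,
    h_current: float,
    *,
    rejected: bool = False,
) -> float:
    """Next step size from the current normalized error.

    Zero error grows by ``facmax``; after a rejection the prediction is
    recomputed from the rejected error and additionally capped at the current
    step.  The factor is always clamped to [facmin, facmax].
    """
    if not h_current > 0:
        raise ValueError(f"h_current must be positive, got {h_current}")
    if combined <= 0.0:
        factor = state.facmax
    elif state.filter == "h211b" and state.err_prev is not None and not rejected:
        # H211b digital filter (b = 4): geometric memory of the last two
        # errors and the last step ratio; smooths the step-size sequence.
        b = 4.0
        beta = state.order_exponent / b
        ratio = h_current / state.h_prev if state.h_prev else 1.0
        factor = (
            (state.safety / combined) ** beta
            * (state.safety / state.err_prev) ** beta
            * ratio ** (-1.0 / b)
        )
    else:
        factor = state.safety * combined ** (-state.order_exponent)
    factor = min(max(factor, state.facmin), state.facmax)
    h_next = factor * h_current
    if rejected:
        h_next = min(h_next, h_current)
    else:
        state.h_prev = h_current
        state.err_prev = combined if combined > 0 else None
    return h_next


def initial_step(
    rhs,
    t0: float,
    x0: np.ndarray,
    u,
    rel_tol: float,
    abs_tol,
    t_total: float,
) -> tuple[float, int]:
    """Conservative first step size; returns ``(h0, rhs_evaluations)``.

    Balances a crude derivative-based bound d0/d1 (the step over which the
    scaled solution changes by about 1%) against a hard ceiling of 1e-4 of
    the total integration time.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    abs_tol = np.broadcast_to(np.asarray(abs_tol, dtype=float), x0.shape)
    scale = rel_tol * np.abs(x0) + abs_tol
    f0 = np.atleast_1d(np.asarray(rhs(t0, x0, u), dtype=float))
    d0 = float(np.max(np.abs(x0) / scale))
    d1 = float(np.max(np.abs(f0) / scale))
    ceiling = 1e-4 * t_total
    if d1 <= 0.0:
        return ceiling, 1
    h0 = 0.01 * max(d0, 1.0) / d1
    return min(h0, ceiling), 1
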