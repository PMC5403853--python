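"""Implicit BDF2 steps on non-uniform grids, with a BDF1 startup step.

The second-order backward differentiation formula on a non-uniform grid reads

    x_{n+1} = alpha1 x_n + alpha2 x_{n-1} + beta h_{n+1} f(t_{n+1}, x_{n+1})

with step ratio gamma = h_{n+1}/h_n and

    alpha2 = -gamma^2 / (2 gamma + 1)
    alpha1 = 1 - alpha2
    beta   = (gamma + 1) / (2 gamma + 1).

At gamma = 1 these reduce to the classic equidistant BDF2 coefficients
(4/3, -1/3, 2/3).  The formula is *decoupled*: exchanged variables from partner
components enter only as values frozen at t_{n+1}, never inside the implicit
solve.

The implicit relation is solved by a damped Newton iteration with a
forward-difference Jacobian that is assembled once per step and reused across
iterations.  Every right-hand-side evaluation — including the n evaluations of
a finite-difference Jacobian — is counted, so the "number of ODE calls" cost
metric is well defined and conservative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .history import ComponentState

__all__ = [
    "BDF2Coefficients",
    "ImplicitSolveReport",
    "bdf2_coefficients",
    "bdf2_step",
    "bdf1_startup_step",
    "IntegratorError",
]

#: Newton convergence threshold on the scaled update norm.  One order below
#: the discretization acceptance threshold (which is 1 in the same norm), so
#: the nonlinear-solve error never pollutes the step-error estimate.
NEWTON_TOL = 0.1
NEWTON_MAX_ITER = 10
_SQRT_EPS = float(np.sqrt(np.finfo(float).eps))


class IntegratorError(RuntimeError):
    """Raised when an implicit solve cannot be completed."""


@dataclass(frozen=True)
class BDF2Coefficients:
    """Step-ratio-dependent coefficients of the non-uniform BDF2 formula."""

    gamma: float
    alpha1: float
    alpha2: float
    beta: float


@dataclass
class ImplicitSolveReport:
    """Outcome of one damped-Newton solve of the implicit step relation."""

    converged: bool
    iterations: int
    residual_norm: float
    rhs_evaluations: int
    jacobian_evaluations: int = 0  # rhs evaluations spent on FD Jacobians


def bdf2_coefficients(h_next: float, h_prev: float) -> BDF2Coefficients:
    """Coefficients of the non-uniform BDF2 step of size ``h_next`` after ``h_prev``."""
    if not h_next > 0 or not h_prev > 0:
        raise IntegratorError(
            f"step sizes must be positive, got h_next={h_next}, h_prev={h_prev}"
        )
    gamma = h_next / h_prev
    alpha2 = -(gamma * gamma) / (2.0 * gamma + 1.0)
    alpha1 = 1.0 - alpha2
    beta = (gamma + 1.0) / (2.0 * gamma + 1.0)
    return BDF2Coefficients(gamma=gamma, alpha1=alpha1, alpha2=alpha2, beta=beta)


def _solve_implicit(
    const: np.ndarray,
    coeff: float,
    t_new: float,
    rhs: Callable,
    u,
    x_guess: np.ndarray,
    scale: np.ndarray,
) -> tuple[np.ndarray, ImplicitSolveReport]:
    """Solve ``x = const + coeff * f(t_new, x, u)`` by damped Newton.

    ``scale`` is the per-component error scale (relTOL*|x| + absTOL); the
    iteration stops when the scaled update norm drops below ``NEWTON_TOL``.
    The Jacobian of ``f`` is approximated by forward differences at the initial
    guess and reused for all iterations of this step.
    """
    n = x_guess.size
    n_rhs = 0
    n_jac = 0

    x = x_guess.astype(float, copy=True)
    f = np.asarray(rhs(t_new, x, u), dtype=float)
    n_rhs += 1

    # Forward-difference Jacobian of f at the predictor, reused across iterations.
    jac = np.empty((n, n))
    for j in range(n):
        delta = _SQRT_EPS * max(abs(x[j]), scale[j])
        if delta == 0.0:
            delta = _SQRT_EPS
        xp = x.copy()
        xp[j] += delta
        fp = np.asarray(rhs(t_new, xp, u), dtype=float)
        jac[:, j] = (fp - f) / delta
    n_rhs += n
    n_jac += n

    newton_mat = np.eye(n) - coeff * jac

    def residual(xv, fv):
        return xv - const - coeff * fv

    res = residual(x, f)
    res_norm = float(np.max(np.abs(res) / scale))
    converged = False
    iterations = 0
    for iterations in range(1, NEWTON_MAX_ITER + 1):
        try:
            dx = np.linalg.solve(newton_mat, -res)
        except np.linalg.LinAlgError as exc:  # singular iteration matrix
            raise IntegratorError(f"singular Newton matrix at t={t_new}") from exc
        update_norm = float(np.max(np.abs(dx) / scale))

        # Damped update: halve the step while the scaled residual grows.
        lam = 1.0
        for _ in range(6):
            x_trial = x + lam * dx
            f_trial = np.asarray(rhs(t_new, x_trial, u), dtype=float)
            n_rhs += 1
            res_trial = residual(x_trial, f_trial)
            trial_norm = float(np.max(np.abs(res_trial) / scale))
            if trial_norm <= res_norm or lam <= 1.0 / 32.0:
                break
            lam *= 0.5
        x, f, res, res_norm = x_trial, f_trial, res_trial, trial_norm
        if lam * update_norm <= NEWTON_TOL:
            converged = True
            break

    report = ImplicitSolveReport(
        converged=converged,
        iterations=iterations,
        residual_norm=res_norm,
        rhs_evaluations=n_rhs,
        jacobian_evaluations=n_jac,
    )
    return x, report


def _error_scale(x: np.ndarray, rel_tol: float, abs_tol) -> np.ndarray:
    abs_tol = np.broadcast_to(np.asarray(abs_tol, dtype=float), x.shape)
    return rel_tol * np.abs(x) + abs_tol


def bdf2_step(
    history: ComponentState,
    h: float,
    rhs: Callable,
    exchanged=None,
    *,
    x_predict: np.ndarray | None = None,
    rel_tol: float = 1e-6,
    abs_tol=1e-9,
) -> tuple[np.ndarray, ImplicitSolveReport]:
    """One implicit BDF2 step of size ``h`` from the newest two history entries.

    ``exchanged`` holds the partner outputs approximated at the new time and is
    passed to ``rhs(t, x, u)`` unchanged (frozen during the Newton iteration).
    ``x_predict`` seeds the Newton iteration; the previous state is used when
    it is not supplied.
    """
    if len(history) < 2:
        raise IntegratorError("BDF2 requires at least 2 history entries")
    if not h > 0:
        raise IntegratorError(f"step size must be positive, got {h}")
    t_n = history.times[-1]
    x_n = history.states[-1]
    x_nm1 = history.states[-2]
    h_prev = history.last_step
    t_new = t_n + h

    coeffs = bdf2_coefficients(h, h_prev)
    const = coeffs.alpha1 * x_n + coeffs.alpha2 * x_nm1
    guess = x_n if x_predict is None else np.asarray(x_predict, dtype=float)
    scale = _error_scale(guess, rel_tol, abs_tol)
    return _solve_implicit(
        const, coeffs.beta * h, t_new, rhs, exchanged, guess, scale
    )


def bdf1_startup_step(
    x0: np.ndarray,
    t0: float,
    h: float,
    rhs: Callable,
    exchanged=None,
    *,
    x_predict: np.ndarray | None = None,
    rel_tol: float = 1e-6,
    abs_tol=1e-9,
) -> tuple[np.ndarray, ImplicitSolveReport]:
    """One backward-Euler step ``x_new = x0 + h f(t0+h, x_new, u)``.

    BDF2 needs two history points; the very first step of every component is
    taken with BDF1 instead.  Non-convergence is raised to the caller.
    """
    if not h > 0:
        raise IntegratorError(f"step size must be positive, got {h}")
    x0 = np.asarray(x0, dtype=float)
    guess = x0 if x_predict is None else np.asarray(x_predict, dtype=float)
    scale = _error_scale(guess, rel_tol, abs_tol)
    x_new, report = _solve_implicit(x0, h, t0 + h, rhs, exchanged, guess, scale)
    if not report.converged:
        raise IntegratorError(
            f"startup BDF1 step did not converge at t={t0 + h} (h={h})"
        )
    return x_new, report
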