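"""Time-stamped solution histories and quadratic approximation of exchanged variables.

A co-simulated component keeps a short, strictly increasing history of its own
solution (the BDF stencil) and of the *exchanged* variables it publishes to its
partners.  Values of a partner's exchanged variables at arbitrary times are
reconstructed from at most three stored samples with a second-order polynomial,
evaluated in Newton (divided-difference) form; the same routine serves both
interpolation inside the sample span and extrapolation beyond it.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "ComponentState",
    "ExchangeRecord",
    "append_state",
    "poly2_eval",
    "classify_query",
    "INTERPOLATION",
    "EXTRAPOLATION",
]

INTERPOLATION = "interpolation"
EXTRAPOLATION = "extrapolation"

#: Default number of retained (time, value) entries.  Three are needed for the
#: quadratic stencil; extra entries are kept so that asynchronous communication
#: can still interpolate across a macro-step boundary after the partner has
#: moved on.
DEFAULT_RETENTION = 8


class HistoryError(ValueError):
    """Raised on violations of the history contracts (non-increasing times, ...)."""


class ComponentState:
    """Bounded history of one component's solution: times and state vectors.

    Times are strictly increasing; the oldest entries are discarded once the
    retention limit is exceeded.  At least two entries must be present before a
    BDF2 step can be formed and at least one before any approximation.
    """

    __slots__ = ("times", "states", "retention")

    def __init__(self, retention: int = DEFAULT_RETENTION):
        if retention < 3:
            raise HistoryError(f"retention must be >= 3, got {retention}")
        self.retention = int(retention)
        self.times: list[float] = []
        self.states: list[np.ndarray] = []

    def __len__(self) -> int:
        return len(self.times)

    @property
    def last_time(self) -> float:
        if not self.times:
            raise HistoryError("history is empty")
        return self.times[-1]

    @property
    def last_state(self) -> np.ndarray:
        if not self.states:
            raise HistoryError("history is empty")
        return self.states[-1]

    @property
    def last_step(self) -> float:
        """Length of the most recent accepted step (needs >= 2 entries)."""
        if len(self.times) < 2:
            raise HistoryError("need at least 2 history entries for a step length")
        return self.times[-1] - self.times[-2]

    def append(self, t: float, x: np.ndarray) -> "ComponentState":
        return append_state(self, t, x)

    def recent(self, k: int = 3) -> list[tuple[float, np.ndarray]]:
        """The newest ``min(k, len)`` entries, oldest first."""
        k = min(k, len(self.times))
        return list(zip(self.times[-k:], self.states[-k:]))

    def snapshot(self) -> tuple:
        """Cheap bitwise snapshot for exact rollback."""
        return (tuple(self.times), tuple(x.copy() for x in self.states))

    def restore(self, snap: tuple) -> None:
        times, states = snap
        self.times = list(times)
        self.states = [x.copy() for x in states]


def append_state(history: ComponentState, t: float, x: np.ndarray) -> ComponentState:
    """Append ``(t, x)`` to ``history`` (in place) enforcing strict monotonicity.

    Entries beyond the retention limit are dropped from the old end.  Returns
    the same ``ComponentState`` for convenience.
    """
    t = float(t)
    if history.times and t <= history.times[-1]:
        raise HistoryError(
            f"non-increasing time: appending t={t!r} after t={history.times[-1]!r}"
        )
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        x = np.atleast_1d(np.squeeze(x))
    if history.states and x.shape != history.states[-1].shape:
        raise HistoryError(
            f"state dimension changed: {x.shape} vs {history.states[-1].shape}"
        )
    history.times.append(t)
    history.states.append(x.copy())
    while len(history.times) > history.retention:
        history.times.pop(0)
        history.states.pop(0)
    return history


class ExchangeRecord:
    """Samples of one component's exchanged (output) variables over time.

    Stores ``(t, g(x))`` pairs published by the source component; partners read
    them back through :func:`poly2_eval` on the newest three samples.
    """

    __slots__ = ("source_id", "times", "values", "retention")

    def __init__(self, source_id: str, retention: int = DEFAULT_RETENTION):
        self.source_id = source_id
        self.retention = int(retention)
        self.times: list[float] = []
        self.values: list[np.ndarray] = []

    def __len__(self) -> int:
        return len(self.times)

    def append(self, t: float, value: np.ndarray) -> None:
        t = float(t)
        if self.times and t <= self.times[-1]:
            raise HistoryError(
                f"non-increasing exchange time for {self.source_id!r}: "
                f"{t!r} after {self.times[-1]!r}"
            )
        value = np.atleast_1d(np.asarray(value, dtype=float))
        if self.values and value.shape != self.values[-1].shape:
            raise HistoryError(
                f"exchanged-variable dimension changed for {self.source_id!r}"
            )
        self.times.append(t)
        self.values.append(value.copy())
        while len(self.times) > self.retention:
            self.times.pop(0)
            self.values.pop(0)

    def recent(self, k: int = 3) -> list[tuple[float, np.ndarray]]:
        k = min(k, len(self.times))
        return list(zip(self.times[-k:], self.values[-k:]))

    def eval_at(self, t: float) -> np.ndarray:
        """Quadratic approximation of the exchanged variables at time ``t``."""
        return poly2_eval(self.recent(3), t)

    def classify(self, t: float) -> str:
        return classify_query(self.recent(3), t)

    def snapshot(self) -> tuple:
        return (tuple(self.times), tuple(v.copy() for v in self.values))

    def restore(self, snap: tuple) -> None:
        times, values = snap
        self.times = list(times)
        self.values = [v.copy() for v in values]


def poly2_eval(
    samples: Sequence[tuple[float, np.ndarray]], t_query: float
) -> np.ndarray:
    """Evaluate the interpolating polynomial through up to three samples.

    With three samples this is the unique quadratic through them, with two the
    linear interpolant, with one the constant.  The polynomial is built in
    Newton divided-difference form, which stays well conditioned on strongly
    non-uniform spacings.  Works for interpolation and extrapolation alike.
    """
    if len(samples) == 0:
        raise HistoryError("poly2_eval requires at least one sample")
    if len(samples) > 3:
        samples = samples[-3:]
    times = [float(t) for t, _ in samples]
    if len(set(times)) != len(times):
        raise HistoryError(f"duplicate sample times in {times}")
    vals = [np.atleast_1d(np.asarray(v, dtype=float)) for _, v in samples]

    # Newton form: c0 + c1 (t - t0) + c2 (t - t0)(t - t1)
    c0 = vals[0]
    if len(samples) == 1:
        return c0.copy()
    c1 = (vals[1] - vals[0]) / (times[1] - times[0])
    result = c0 + c1 * (t_query - times[0])
    if len(samples) == 3:
        d12 = (vals[2] - vals[1]) / (times[2] - times[1])
        c2 = (d12 - c1) / (times[2] - times[0])
        result = result + c2 * (t_query - times[0]) * (t_query - times[1])
    return result


def classify_query(
    samples: Sequence[tuple[float, np.ndarray]], t_query: float
) -> str:
    """Label a query as interpolation or extrapolation relative to the samples.

    A query exactly at a sample-span endpoint counts as interpolation (boundary
    inclusive).  Used for diagnostics of the coupling strategies.
    """
    if len(samples) == 0:
        raise HistoryError("classify_query requires at least one sample")
    times = [float(t) for t, _ in samples]
    if min(times) <= t_query <= max(times):
        return INTERPOLATION
    return EXTRAPOLATION
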