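"""CUSUM trajectory computation: recursion, alarms, resets, run summaries.

The chart statistic follows the truncated-at-zero recursion

    C_0 = 0,   C_t = max(0, C_{t-1} + W_t),   t = 1, 2, ...

and an alarm fires whenever ``C_t >= h`` (the control limit).  The
non-strict rule is deliberate: a zero control limit then signals at every
observation, which is the behaviour reported for degenerate small-volume,
low-risk charts.  Comparisons against ``h`` use an absolute floating-point
tolerance so that attainable maxima sitting exactly on the limit are
classified stably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .indicators import WeightPair

__all__ = [
    "LIMIT_TOL",
    "NO_SIGNAL",
    "CusumRun",
    "resolve_weights",
    "run_unrestricted",
    "run_monitored",
    "max_statistic",
    "time_to_signal",
]

#: absolute tolerance for comparisons against the control limit
LIMIT_TOL = 1e-12

#: sentinel returned by :func:`time_to_signal` when no alarm occurs within n
NO_SIGNAL = None

ResetPolicy = Literal["none", "to_zero", "to_value"]


@dataclass
class CusumRun:
    """One computed CUSUM trajectory.

    ``statistics`` holds C_0..C_n (length n+1, C_0 = 0); ``weights_applied``
    holds W_1..W_n; ``alarms`` holds the strictly increasing 1-based indices
    t at which C_t reached the control limit (empty for unrestricted runs).
    """

    statistics: np.ndarray
    weights_applied: np.ndarray
    outcomes: np.ndarray
    limit: float | None = None
    alarms: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    reset_policy: ResetPolicy = "none"
    reset_value: float = 0.0

    @property
    def n(self) -> int:
        return len(self.outcomes)

    @property
    def max_statistic(self) -> float:
        return float(np.max(self.statistics[1:])) if self.n else 0.0

    @property
    def final_statistic(self) -> float:
        return float(self.statistics[-1])

    def to_frame(self):
        """Per-observation detail table (t, y, W_t, C_t, alarm flag)."""
        import pandas as pd

        t = np.arange(1, self.n + 1)
        alarm = np.zeros(self.n, dtype=bool)
        if self.alarms.size:
            alarm[self.alarms - 1] = True
        return pd.DataFrame(
            {
                "t": t,
                "y": self.outcomes,
                "weight": self.weights_applied,
                "cusum": self.statistics[1:],
                "alarm": alarm,
            }
        )


def resolve_weights(
    outcomes: np.ndarray,
    weight_source: WeightPair | tuple[np.ndarray, np.ndarray] | np.ndarray,
) -> np.ndarray:
    """Map outcomes to applied weights W_1..W_n.

    ``weight_source`` is either a :class:`~berncusum.indicators.WeightPair`
    (crude chart), a ``(w_success, w_failure)`` pair of per-observation
    arrays (risk-adjusted chart), or a ready-made array of applied weights.
    """
    n = outcomes.shape[0]
    if isinstance(weight_source, WeightPair):
        return np.asarray(weight_source.applied(outcomes), dtype=float)
    if isinstance(weight_source, tuple):
        w_success, w_failure = (np.asarray(w, dtype=float) for w in weight_source)
        if w_success.shape[0] != n or w_failure.shape[0] != n:
            raise ValueError(
                f"per-observation weights (len {w_success.shape[0]}) do not align "
                f"with outcomes (len {n})"
            )
        return np.where(outcomes == 1, w_failure, w_success)
    weights = np.asarray(weight_source, dtype=float)
    if weights.shape[0] != n:
        raise ValueError(f"weights (len {weights.shape[0]}) do not align with outcomes (len {n})")
    return weights


def _validate_outcomes(outcomes: Sequence[int] | np.ndarray) -> np.ndarray:
    y = np.asarray(outcomes)
    if y.size == 0:
        raise ValueError("outcome sequence is empty")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    return y.astype(np.int8)


def run_unrestricted(
    outcomes: Sequence[int] | np.ndarray,
    weight_source: WeightPair | tuple[np.ndarray, np.ndarray] | np.ndarray,
) -> CusumRun:
    """Compute a CUSUM run with no control limit and no resets.

    Used by the control-limit simulation, whose candidate limits are the
    maxima of such runs.
    """
    y = _validate_outcomes(outcomes)
    weights = resolve_weights(y, weight_source)
    stats = np.empty(y.shape[0] + 1)
    stats[0] = 0.0
    c = 0.0
    for t, w in enumerate(weights, start=1):
        c = max(0.0, c + w)
        stats[t] = c
    return CusumRun(statistics=stats, weights_applied=weights, outcomes=y)


def run_monitored(
    outcomes: Sequence[int] | np.ndarray,
    weight_source: WeightPair | tuple[np.ndarray, np.ndarray] | np.ndarray,
    h: float,
    reset_policy: ResetPolicy = "to_zero",
    reset_value: float = 0.0,
) -> CusumRun:
    """Run the chart against control limit ``h``, recording alarms.

    An alarm fires at t when ``C_t >= h`` (within :data:`LIMIT_TOL`).  After
    an alarm the statistic is reset according to ``reset_policy`` before
    observation t+1 is processed: ``to_zero`` restarts at 0 (the default),
    ``to_value`` restarts at ``reset_value`` (a head-start below h, giving
    faster subsequent alarms), ``none`` leaves the trajectory untouched and
    merely records every limit crossing.
    """
    if h < 0.0:
        raise ValueError(f"control limit h must be nonnegative, got {h!r}")
    if reset_policy == "to_value" and reset_value >= h - LIMIT_TOL:
        raise ValueError(
            f"reset value {reset_value} >= control limit {h}: the chart would alarm forever"
        )
    y = _validate_outcomes(outcomes)
    weights = resolve_weights(y, weight_source)
    stats = np.empty(y.shape[0] + 1)
    stats[0] = 0.0
    alarms: list[int] = []
    c = 0.0
    for t, w in enumerate(weights, start=1):
        c = max(0.0, c + w)
        stats[t] = c
        if c >= h - LIMIT_TOL:
            alarms.append(t)
            if reset_policy == "to_zero":
                c = 0.0
            elif reset_policy == "to_value":
                c = reset_value
    return CusumRun(
        statistics=stats,
        weights_applied=weights,
        outcomes=y,
        limit=float(h),
        alarms=np.asarray(alarms, dtype=np.int64),
        reset_policy=reset_policy,
        reset_value=reset_value,
    )


def max_statistic(run: CusumRun) -> float:
    """Maximum of C_1..C_n — the candidate control limit this run attains."""
    return run.max_statistic


def time_to_signal(run: CusumRun) -> int | None:
    """1-based index of the first alarm, or :data:`NO_SIGNAL` if none fired within n."""
    if run.alarms.size == 0:
        return NO_SIGNAL
    return int(run.alarms[0])
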