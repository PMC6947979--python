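"""Control limits calibrated to a false-alarm probability.

The false-alarm probability of a chart monitored over one period of ``n``
observations is ``P(max_t C_t >= h)`` under in-control data.  There is no
closed form for the Bernoulli CUSUM, so the limit ``h`` is found from the
distribution of the *unrestricted-run maximum*:

1. simulate many in-control outcome sequences of length ``n`` (crude:
   Bernoulli(c0); risk-adjusted: risks resampled with replacement from the
   Phase-I population, a fresh case mix per run);
2. compute unrestricted CUSUM runs (no limit, no resets);
3. collect the maximum statistic of each run;
4. pick ``h`` from the upper tail of the maxima so that the fraction of
   maxima reaching ``h`` matches the target false-alarm probability.

Because the maximum has discrete support, only *attainable* maxima are
candidate limits — any ``h`` between two attainable values behaves
identically, so the attainable value is canonical.  The selection rule is
conservative: the smallest attainable ``m`` with ``P(max >= m) <= alpha``,
which under the ``>=`` alarm rule guarantees an achieved false-alarm
probability at or below target.  When the support gap around the target is
so wide that this choice undershoots ``alpha`` by more than half (rare
events at small volume), the selection collapses one candidate down — the
limit a straight (1-alpha) percentile of the maxima would give — and the
result is flagged degenerate, since no attainable limit then meets the
target closely.

For small volumes the tail probabilities can be computed exactly by
enumerating all 2^n outcome paths; :func:`exact_control_limit_table`
tabulates every attainable limit with its exact false-alarm probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .engine import LIMIT_TOL
from .indicators import (
    CrudeIndicator,
    RiskAdjustedIndicator,
    st_weights,
)
from .simulate import RiskPopulation

__all__ = [
    "ControlLimitResult",
    "simulate_maxima",
    "simulate_control_limit",
    "exact_control_limit_table",
    "select_exact_limit",
    "ENUMERATION_MAX_N",
]

#: largest volume for which full 2^n path enumeration is offered
ENUMERATION_MAX_N = 20

Indicator = CrudeIndicator | RiskAdjustedIndicator


@dataclass(frozen=True)
class ControlLimitResult:
    """A control limit with its achieved false-alarm probability.

    ``degenerate`` marks limits (h = 0 or the weight of a single adverse
    event) whose achieved false-alarm probability cannot be brought close
    to the target because the chart's discrete support leaves a gap there.
    """

    h: float
    target_alpha: float
    achieved_alpha: float
    n: int
    method: Literal["simulated", "exact"]
    n_runs: int | None = None
    degenerate: bool = False
    indicator_id: str | None = None
    delta: float | None = None

    def __post_init__(self) -> None:
        if self.h < 0.0:
            raise ValueError("control limit must be nonnegative")
        if not 0.0 < self.target_alpha < 1.0:
            raise ValueError("target_alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------
# vectorized batch machinery (shared with the evaluation module)
# ---------------------------------------------------------------------------


def _batch_statistics(weights: np.ndarray) -> np.ndarray:
    """Trajectories C_1..C_n for a (runs, n) weight matrix.

    Uses the reflection identity C_t = S_t - min(0, min_{s<=t} S_s) of the
    truncated recursion, which vectorizes over runs and time.
    """
    s = np.cumsum(weights, axis=1)
    floor = np.minimum(np.minimum.accumulate(s, axis=1), 0.0)
    return s - floor


def _in_control_weights(
    indicator: Indicator, n: int, delta: float, n_runs: int, rng: np.random.Generator
) -> np.ndarray:
    """(runs, n) matrix of applied in-control chart weights."""
    return _shifted_weights(indicator, n, delta, 1.0, n_runs, rng)


def _shifted_weights(
    indicator: Indicator,
    n: int,
    delta_design: float,
    delta_true: float,
    n_runs: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(runs, n) applied weights: chart designed at ``delta_design``, data at ``delta_true``."""
    from .simulate import shifted_probability

    if isinstance(indicator, CrudeIndicator):
        pair = st_weights(indicator.c0, delta_design)
        prob = shifted_probability(indicator.c0, delta_true)
        y = rng.random((n_runs, n)) < prob
        return np.where(y, pair.w_failure, pair.w_success)
    p = rng.choice(indicator.risk_scores, size=(n_runs, n), replace=True)
    denom = 1.0 - p + delta_design * p
    prob = shifted_probability(p, delta_true)
    y = rng.random((n_runs, n)) < prob
    return np.where(y, np.log(delta_design) - np.log(denom), -np.log(denom))


def simulate_maxima(
    indicator: Indicator | RiskPopulation,
    n: int,
    delta: float,
    n_runs: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Maximum CUSUM statistics of ``n_runs`` simulated in-control unrestricted runs."""
    if isinstance(indicator, RiskPopulation):
        indicator = indicator.to_indicator()
    if n < 1:
        raise ValueError("volume n must be at least 1")
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    rng = np.random.default_rng(seed)
    weights = _in_control_weights(indicator, int(n), float(delta), int(n_runs), rng)
    return np.max(_batch_statistics(weights), axis=1)


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------

#: achieved/target ratio below which the conservative candidate is judged
#: to sit across a support gap and the selection collapses one step down
_GAP_RATIO = 0.5


def _select_candidate(
    candidates: np.ndarray, tail_probs: np.ndarray, target_alpha: float
) -> tuple[float, float, bool]:
    """Pick h from attainable candidates and their tail probabilities.

    ``tail_probs[i] = P(max >= candidates[i])``, non-increasing.  Returns
    ``(h, achieved_alpha, degenerate)``.
    """
    meets = np.nonzero(tail_probs <= target_alpha)[0]
    if meets.size == 0:
        # target below the resolution of the tail: report the widest limit
        return float(candidates[-1]), float(tail_probs[-1]), True
    i = int(meets[0])
    if i > 1 and tail_probs[i] < _GAP_RATIO * target_alpha:
        # support gap straddles the target; fall back to the percentile
        # choice one attainable candidate down (achieved > target).  Never
        # past the smallest positive candidate: a zero limit alarms at
        # every observation and is no fallback.
        return float(candidates[i - 1]), float(tail_probs[i - 1]), True
    return float(candidates[i]), float(tail_probs[i]), False


def _candidate_table(maxima: np.ndarray, probs: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Distinct attainable maxima (0 prepended) and their tail probabilities.

    ``probs`` gives each maximum's probability mass (exact enumeration);
    when absent every maximum carries equal Monte-Carlo weight.  Values are
    grouped at the engine's limit tolerance.
    """
    grouped = np.round(maxima / LIMIT_TOL) * LIMIT_TOL
    if probs is None:
        probs = np.full(grouped.shape, 1.0 / grouped.size)
    values, inverse = np.unique(grouped, return_inverse=True)
    mass = np.bincount(inverse, weights=probs)
    if values[0] > 0.0:
        values = np.concatenate(([0.0], values))
        mass = np.concatenate(([0.0], mass))
    tails = np.cumsum(mass[::-1])[::-1]
    tails[0] = 1.0  # P(max >= 0) is 1 by construction
    return values, tails


def simulate_control_limit(
    indicator: Indicator | RiskPopulation,
    n: int,
    delta: float,
    target_alpha: float,
    n_runs: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> ControlLimitResult:
    """Monte-Carlo control limit for volume ``n`` at a target false-alarm probability.

    Runs the four-step simulation algorithm described in the module
    docstring.  Reproducible: a fixed ``seed`` yields a bit-identical
    result.  Degenerate small-volume cases (no attainable limit close to
    the target) are returned flagged, with a warning.
    """
    if isinstance(indicator, RiskPopulation):
        indicator = indicator.to_indicator()
    if not 0.0 < target_alpha < 1.0:
        raise ValueError("target_alpha must lie in (0, 1)")
    maxima = simulate_maxima(indicator, n, delta, n_runs=n_runs, seed=seed)
    candidates, tails = _candidate_table(maxima)
    h, achieved, degenerate = _select_candidate(candidates, tails, target_alpha)
    if degenerate:
        warnings.warn(
            f"no attainable control limit meets alpha={target_alpha} closely at n={n} "
            f"(achieved {achieved:.4g}); the chart's discrete support leaves a gap",
            stacklevel=2,
        )
    return ControlLimitResult(
        h=h,
        target_alpha=float(target_alpha),
        achieved_alpha=achieved,
        n=int(n),
        method="simulated",
        n_runs=int(n_runs),
        degenerate=degenerate,
        indicator_id=indicator.id,
        delta=float(delta),
    )


# ---------------------------------------------------------------------------
# exact enumeration for small volumes
# ---------------------------------------------------------------------------


def exact_control_limit_table(
    indicator: Indicator | RiskPopulation,
    n: int,
    delta: float,
    risk_scores: np.ndarray | None = None,
    chunk: int = 1 << 16,
) -> pd.DataFrame:
    """Every attainable control limit with its exact false-alarm probability.

    Enumerates all ``2^n`` outcome paths (``n <= 20``) with their in-control
    probabilities and tabulates ``P(max >= h)`` for each distinct attainable
    unrestricted-run maximum ``h`` (plus 0, where the probability is 1).

    For a risk-adjusted indicator the patient order is *fixed*: pass the
    ``n`` risk scores via ``risk_scores`` (defaults to the first ``n``
    population scores).  This differs from the simulated limit, which
    integrates over case-mix resampling.
    """
    if isinstance(indicator, RiskPopulation):
        indicator = indicator.to_indicator()
    n = int(n)
    if n < 1:
        raise ValueError("volume n must be at least 1")
    if n > ENUMERATION_MAX_N:
        raise ValueError(
            f"n={n} too large for 2^n path enumeration (max {ENUMERATION_MAX_N}); "
            "use simulate_control_limit instead"
        )
    if isinstance(indicator, CrudeIndicator):
        pair = st_weights(indicator.c0, delta)
        w_success = np.full(n, pair.w_success)
        w_failure = np.full(n, pair.w_failure)
        p_t = np.full(n, indicator.c0)
    else:
        if risk_scores is None:
            if indicator.risk_scores.size < n:
                raise ValueError("population smaller than n; pass risk_scores explicitly")
            risk_scores = indicator.risk_scores[:n]
        p_t = np.asarray(risk_scores, dtype=float)
        if p_t.shape != (n,):
            raise ValueError(f"risk_scores must have length n={n}")
        denom = 1.0 - p_t + delta * p_t
        w_success = -np.log(denom)
        w_failure = np.log(delta) - np.log(denom)

    bits = np.arange(n)
    log_p = np.log(p_t)
    log_q = np.log1p(-p_t)
    all_maxima: list[np.ndarray] = []
    all_probs: list[np.ndarray] = []
    for start in range(0, 1 << n, chunk):
        idx = np.arange(start, min(start + chunk, 1 << n), dtype=np.int64)
        y = ((idx[:, None] >> bits) & 1).astype(bool)
        weights = np.where(y, w_failure, w_success)
        all_maxima.append(np.max(_batch_statistics(weights), axis=1))
        all_probs.append(np.exp(np.where(y, log_p, log_q).sum(axis=1)))
    candidates, tails = _candidate_table(
        np.concatenate(all_maxima), np.concatenate(all_probs)
    )
    return pd.DataFrame({"h": candidates, "exact_alpha": tails})


def select_exact_limit(
    table: pd.DataFrame,
    target_alpha: float,
    n: int | None = None,
    indicator_id: str | None = None,
    delta: float | None = None,
) -> ControlLimitResult:
    """Choose a control limit from an exact candidate table.

    Applies the same conservative-with-collapse selection rule as the
    Monte-Carlo path, against exact tail probabilities.
    """
    if len(table) == 0:
        raise ValueError("candidate table is empty")
    if not 0.0 < target_alpha < 1.0:
        raise ValueError("target_alpha must lie in (0, 1)")
    candidates = table["h"].to_numpy(dtype=float)
    tails = table["exact_alpha"].to_numpy(dtype=float)
    order = np.argsort(candidates)
    candidates, tails = candidates[order], tails[order]
    h, achieved, degenerate = _select_candidate(candidates, tails, target_alpha)
    return ControlLimitResult(
        h=h,
        target_alpha=float(target_alpha),
        achieved_alpha=achieved,
        n=int(n) if n is not None else int(len(table)),
        method="exact",
        degenerate=degenerate,
        indicator_id=indicator_id,
        delta=delta,
    )
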