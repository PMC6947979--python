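"""Performance indicators and CUSUM weight formulas.

A monitored hospital performance indicator is a sequence of dichotomous
outcomes (``y = 0`` success, ``y = 1`` adverse event).  Two flavours are
supported:

* :class:`CrudeIndicator` — a constant baseline failure probability ``c0``
  applies to every patient (ST-CUSUM).
* :class:`RiskAdjustedIndicator` — each patient carries an individual risk
  score ``p`` from a Phase-I risk model; the chart weights are
  individualized (RA-CUSUM).

The chart is tuned to detect a multiplicative shift of the outcome *odds*
by a detection level ``delta`` (odds-ratio multiplier, ``delta > 1`` for
deterioration, ``delta < 1`` for improvement).  The per-observation chart
weights are Bernoulli log-likelihood ratios of the shifted against the
baseline process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CrudeIndicator",
    "RiskAdjustedIndicator",
    "DetectionLevel",
    "WeightPair",
    "alternative_failure_probability",
    "st_weights",
    "ra_weight",
    "ra_weight_pairs",
    "estimate_phase1",
    "indicator_from_config",
]


def _check_probability(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 < value < 1.0:
        raise ValueError(f"{name} must lie strictly in (0, 1), got {value!r}")
    return value


def _check_delta(delta: float) -> float:
    delta = float(delta)
    if not delta > 0.0:
        raise ValueError(f"detection level delta must be positive, got {delta!r}")
    return delta


@dataclass(frozen=True)
class CrudeIndicator:
    """A crude (non-risk-adjusted) indicator with baseline failure probability ``c0``."""

    id: str
    c0: float

    def __post_init__(self) -> None:
        _check_probability(self.c0, "c0")

    @property
    def risk_adjusted(self) -> bool:
        return False


@dataclass(frozen=True)
class RiskAdjustedIndicator:
    """A risk-adjusted indicator defined by its Phase-I case-mix population.

    ``risk_scores`` is the population of per-patient risk probabilities the
    control-limit simulation resamples from (with replacement).  The scores
    are consumed as given; fitting the underlying risk model is outside this
    package's remit.
    """

    id: str
    risk_scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        scores = np.asarray(self.risk_scores, dtype=float)
        if scores.ndim != 1 or scores.size == 0:
            raise ValueError("risk_scores must be a nonempty 1-d collection")
        if not (np.all(scores > 0.0) and np.all(scores < 1.0)):
            raise ValueError("every risk score must lie strictly in (0, 1)")
        object.__setattr__(self, "risk_scores", scores)

    @property
    def risk_adjusted(self) -> bool:
        return True

    @property
    def mean_risk(self) -> float:
        return float(np.mean(self.risk_scores))


@dataclass(frozen=True)
class DetectionLevel:
    """Odds-ratio multiplier the chart is tuned to detect (R_A against R_0 = 1)."""

    delta: float

    def __post_init__(self) -> None:
        _check_delta(self.delta)

    @property
    def deterioration(self) -> bool:
        return self.delta > 1.0


@dataclass(frozen=True)
class WeightPair:
    """CUSUM weights applied per observation: ``w_success`` if y=0, ``w_failure`` if y=1."""

    w_success: float
    w_failure: float

    def applied(self, y: int | np.ndarray) -> np.ndarray:
        """Weight(s) for outcome(s) ``y`` in {0, 1}."""
        return np.where(np.asarray(y) == 1, self.w_failure, self.w_success)


def alternative_failure_probability(c0: float, delta: float) -> float:
    """Failure probability after multiplying the baseline odds by ``delta``.

    ``c_A = delta * o0 / (1 + delta * o0)`` with ``o0 = c0 / (1 - c0)``.
    This is the smallest unacceptable failure probability the ST-CUSUM is
    designed to detect.
    """
    c0 = _check_probability(c0, "c0")
    delta = _check_delta(delta)
    odds = delta * c0 / (1.0 - c0)
    return odds / (1.0 + odds)


def st_weights(c0: float, delta: float) -> WeightPair:
    """Log-likelihood-ratio weights for the crude (ST) chart.

    ``w_failure = log(c_A / c0)``, ``w_success = log((1 - c_A) / (1 - c0))``
    where ``c_A`` shifts the baseline odds by ``delta``.  For ``delta > 1``
    an adverse event pushes the chart up (``w_failure > 0``) and a success
    pulls it towards zero (``w_success < 0``).

    Computed through the equivalent form ``w = log(delta^y) - log(1 - c0 +
    delta*c0)``, which avoids reconstructing ``c_A`` (no cancellation near
    the boundaries), is exactly zero at ``delta = 1``, and coincides bit
    for bit with :func:`ra_weight` at constant risk ``p = c0``.
    """
    c0 = _check_probability(c0, "c0")
    delta = _check_delta(delta)
    denom = 1.0 - c0 + delta * c0
    return WeightPair(
        w_success=-math.log(denom),
        w_failure=math.log(delta) - math.log(denom),
    )


def ra_weight(p: float, r_a: float, y: int) -> float:
    """Risk-adjusted CUSUM weight for one patient.

    ``log(1 / (1 - p + R_A p))`` for a success and
    ``log(R_A / (1 - p + R_A p))`` for an adverse event; with a constant
    ``p = c0`` and ``R_A = delta`` these reduce exactly to :func:`st_weights`.
    """
    p = _check_probability(p, "p")
    r_a = _check_delta(r_a)
    if y not in (0, 1):
        raise ValueError(f"outcome y must be 0 or 1, got {y!r}")
    denom = 1.0 - p + r_a * p
    if y == 1:
        return math.log(r_a) - math.log(denom)
    return -math.log(denom)


def ra_weight_pairs(p: Sequence[float] | np.ndarray, r_a: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-patient weight pairs ``(w_success, w_failure)`` for risk scores ``p``."""
    p = np.asarray(p, dtype=float)
    if p.size and not (np.all(p > 0.0) and np.all(p < 1.0)):
        raise ValueError("every risk score must lie strictly in (0, 1)")
    r_a = _check_delta(r_a)
    denom = 1.0 - p + r_a * p
    return -np.log(denom), np.log(r_a) - np.log(denom)


def estimate_phase1(
    outcomes: Sequence[int] | np.ndarray,
    risk_scores: Sequence[float] | np.ndarray | None = None,
    *,
    id: str = "indicator",
) -> CrudeIndicator | RiskAdjustedIndicator:
    """Phase-I estimation from a historical monitoring period.

    Crude path: the pooled failure rate becomes ``c0``.  Risk-adjusted path
    (``risk_scores`` given): the scores themselves become the resampling
    population for control-limit simulation.

    Raises on an empty sequence and on degenerate all-0/all-1 outcomes,
    for which the crude estimate would leave the open interval (0, 1).
    """
    y = np.asarray(outcomes)
    if y.size == 0:
        raise ValueError("Phase-I outcome sequence is empty")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcomes must be binary (0 = success, 1 = adverse event)")
    if risk_scores is not None:
        scores = np.asarray(risk_scores, dtype=float)
        if scores.shape != y.shape:
            raise ValueError("risk_scores must align 1:1 with outcomes")
        return RiskAdjustedIndicator(id=id, risk_scores=scores)
    c0 = float(np.mean(y))
    if c0 <= 0.0 or c0 >= 1.0:
        raise ValueError(
            "all-success or all-failure Phase-I data: pooled failure rate "
            f"{c0} leaves (0, 1); supply c0 explicitly or pool more data"
        )
    return CrudeIndicator(id=id, c0=c0)


def indicator_from_config(cfg: dict) -> CrudeIndicator | RiskAdjustedIndicator:
    """Build an indicator from a key-value config (parsed YAML/JSON).

    Expected keys: ``id``; ``type`` (``crude`` or ``risk_adjusted``); for a
    crude indicator ``c0``; for a risk-adjusted one either ``risk_scores``
    (inline list) or ``risk_scores_csv`` + optional ``column`` (default
    ``p``) naming a CSV file to read the score column from.
    """
    kind = str(cfg.get("type", "crude")).lower().replace("-", "_")
    label = str(cfg.get("id", "indicator"))
    if kind == "crude":
        if "c0" not in cfg:
            raise ValueError("crude indicator config requires key 'c0'")
        return CrudeIndicator(id=label, c0=float(cfg["c0"]))
    if kind in ("risk_adjusted", "ra"):
        if "risk_scores" in cfg:
            scores = np.asarray(cfg["risk_scores"], dtype=float)
        elif "risk_scores_csv" in cfg:
            import pandas as pd

            column = cfg.get("column", "p")
            frame = pd.read_csv(cfg["risk_scores_csv"])
            if column not in frame.columns:
                raise ValueError(f"column {column!r} not found in {cfg['risk_scores_csv']!r}")
            scores = frame[column].to_numpy(dtype=float)
        else:
            raise ValueError(
                "risk-adjusted indicator config requires 'risk_scores' or 'risk_scores_csv'"
            )
        return RiskAdjustedIndicator(id=label, risk_scores=scores)
    raise ValueError(f"unknown indicator type {cfg.get('type')!r}")
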