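"""Synthetic hospital performance data.

Generates the in-control and out-of-control Bernoulli outcome streams the
simulation studies run on, standing in for statutory external-quality-
assurance (EQA) per-patient records: crude streams at a constant baseline
failure probability, and risk-adjusted streams whose per-patient risks are
resampled with replacement from a Phase-I case-mix population, optionally
restricted to its low- or high-risk quartile.

Out-of-control truth is a uniform odds multiplier ``delta_true`` applied to
every patient's failure odds — exactly the alternative the risk-adjusted
chart weights test against.

The module-level study constants (baseline failure probabilities, hospital
volumes, false-alarm probabilities, detection levels) are the default
conditions of the package's simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .indicators import CrudeIndicator, RiskAdjustedIndicator, _check_delta, _check_probability

__all__ = [
    "RiskPopulation",
    "shifted_probability",
    "generate_crude_stream",
    "generate_ra_stream",
    "stratify_population",
    "demo_risk_population",
    "STUDY_VOLUMES",
    "STUDY_ALPHAS",
    "STUDY_DELTAS",
    "STUDY_INDICATORS",
]

#: hospital volumes of the simulation study: small / medium / large
STUDY_VOLUMES = (7, 42, 105)
#: false-alarm probabilities the control limits are calibrated to
STUDY_ALPHAS = (0.001, 0.005, 0.01, 0.05)
#: detection levels (odds-ratio multipliers) around a doubling of odds
STUDY_DELTAS = (1.5, 2.0, 2.5, 3.0)
#: crude study indicators: rare neonatal surgery events and delayed
#: femur-fracture surgery, at their pooled baseline failure probabilities
STUDY_INDICATORS = {
    "neonatal_nec_surgery": CrudeIndicator(id="neonatal_nec_surgery", c0=0.0125),
    "femur_fracture_delay": CrudeIndicator(id="femur_fracture_delay", c0=0.1921),
}

Stratum = Literal["mixed", "low", "high"]


@dataclass(frozen=True)
class RiskPopulation:
    """A case-mix population of per-patient risk probabilities.

    ``stratum`` records whether the scores are the full population or its
    low-/high-risk quartile; ``cutoffs`` are the (lower, upper) quartile
    values of the source population used for stratification.
    """

    scores: np.ndarray
    stratum: Stratum = "mixed"
    cutoffs: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.size == 0:
            raise ValueError("risk population is empty")
        if not (np.all(scores > 0.0) and np.all(scores < 1.0)):
            raise ValueError("risk scores must lie strictly in (0, 1)")
        object.__setattr__(self, "scores", scores)

    @property
    def mean_risk(self) -> float:
        return float(np.mean(self.scores))

    def to_indicator(self, id: str = "risk_adjusted") -> RiskAdjustedIndicator:
        return RiskAdjustedIndicator(id=id, risk_scores=self.scores)


def shifted_probability(p: float | np.ndarray, delta_true: float) -> float | np.ndarray:
    """Failure probability after multiplying the odds of ``p`` by ``delta_true``.

    The identity ``odds(shifted) = delta_true * odds(p)`` holds exactly:
    ``shifted = delta_true * p / (1 - p + delta_true * p)``.
    """
    delta_true = _check_delta(delta_true)
    p = np.asarray(p, dtype=float) if not np.isscalar(p) else p
    return delta_true * p / (1.0 - p + delta_true * p)


def _as_frame(
    hospital_id: str, y: np.ndarray, p: np.ndarray | None, meta: dict
) -> pd.DataFrame:
    frame = pd.DataFrame({"hospital_id": hospital_id, "t": np.arange(1, len(y) + 1), "y": y})
    if p is not None:
        frame["p"] = p
    frame.attrs.update(meta)
    return frame


def generate_crude_stream(
    c0: float,
    n: int,
    delta_true: float = 1.0,
    seed: int | np.random.Generator | None = None,
    hospital_id: str = "H1",
) -> pd.DataFrame:
    """I.i.d. Bernoulli outcome stream at baseline ``c0`` with odds shifted by ``delta_true``.

    ``delta_true = 1`` generates in-control data at failure probability
    ``c0``; larger values deteriorate the process.  Returns a tidy frame
    with columns ``hospital_id, t, y`` (t contiguous from 1).
    """
    _check_probability(c0, "c0")
    rng = np.random.default_rng(seed)
    prob = shifted_probability(c0, delta_true)
    y = (rng.random(int(n)) < prob).astype(np.int8)
    return _as_frame(hospital_id, y, None, {"c0": c0, "delta_true": delta_true})


def generate_ra_stream(
    population: RiskPopulation | Sequence[float] | np.ndarray,
    n: int,
    delta_true: float = 1.0,
    seed: int | np.random.Generator | None = None,
    hospital_id: str = "H1",
) -> pd.DataFrame:
    """Risk-adjusted outcome stream: resample risks, then draw outcomes.

    Per patient, a risk score ``p`` is drawn with replacement from the
    population; the outcome is Bernoulli at ``p`` when in control and at
    the odds-shifted probability when ``delta_true != 1``.  The frame
    carries the *Phase-I* score ``p`` (the chart never sees the shift).
    """
    if not isinstance(population, RiskPopulation):
        population = RiskPopulation(scores=np.asarray(population, dtype=float))
    rng = np.random.default_rng(seed)
    p = rng.choice(population.scores, size=int(n), replace=True)
    prob = shifted_probability(p, delta_true)
    y = (rng.random(int(n)) < prob).astype(np.int8)
    return _as_frame(hospital_id, y, p, {"stratum": population.stratum, "delta_true": delta_true})


def stratify_population(
    scores: Sequence[float] | np.ndarray, stratum: Stratum = "mixed"
) -> RiskPopulation:
    """Restrict a score population to a case-mix stratum.

    ``high`` keeps scores at or above the upper quartile, ``low`` at or
    below the lower quartile, ``mixed`` keeps everything.  Quartiles use
    the nearest-rank (inverted empirical CDF) convention, and ties on the
    cutoff are included — matching closed cutoff definitions such as
    "upper 25th percentile (>= 1.04%)".
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("score population is empty")
    lower = float(np.quantile(scores, 0.25, method="inverted_cdf"))
    upper = float(np.quantile(scores, 0.75, method="inverted_cdf"))
    if stratum == "mixed":
        kept = scores
    elif stratum == "low":
        kept = scores[scores <= lower]
    elif stratum == "high":
        kept = scores[scores >= upper]
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    if kept.size == 0:
        raise ValueError(f"stratum {stratum!r} is empty for this population")
    return RiskPopulation(scores=kept, stratum=stratum, cutoffs=(lower, upper))


def demo_risk_population(
    size: int = 10_000, seed: int | np.random.Generator | None = None
) -> RiskPopulation:
    """Synthetic carotid-surgery-like case mix (illustrative fixture).

    A two-component beta mixture calibrated so that the bulk of risks sits
    below 2% with a median near 0.8% and a small high-risk tail reaching
    ~40% — the shape of published per-patient stroke/death risk scores for
    open carotid stenosis surgery.  Purely synthetic; used for demos and
    as a realistic default in simulation studies, never as ground truth.
    """
    rng = np.random.default_rng(seed)
    heavy = rng.random(int(size)) < 0.08
    scores = np.where(
        heavy,
        rng.beta(1.5, 15.0, int(size)),
        rng.beta(2.0, 240.0, int(size)),
    )
    return RiskPopulation(scores=np.clip(scores, 0.0024, 0.41))
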