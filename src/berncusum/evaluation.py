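"""Alarm characteristics of a chart configuration, by simulation.

Given an indicator, a volume ``n``, a design detection level and a control
limit, this module estimates the probability that the chart signals within
one monitoring period — under in-control data (the realized false-alarm
probability) and under data generated at a shifted odds multiplier
``delta_true`` (the chart's power) — together with the distribution of the
time to signal.  "Signalling within the period" means the first alarm index
``t_s <= n``; with the reset-to-zero policy the first-alarm event is
unchanged by resets, so unrestricted first passages are used internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .engine import LIMIT_TOL
from .indicators import CrudeIndicator, RiskAdjustedIndicator
from .limits import _batch_statistics, _shifted_weights, simulate_control_limit
from .simulate import RiskPopulation

__all__ = [
    "SignalRateEstimate",
    "RunLengthSample",
    "estimate_signal_rate",
    "power_grid",
]

Indicator = CrudeIndicator | RiskAdjustedIndicator


@dataclass(frozen=True)
class RunLengthSample:
    """Times to signal from simulated monitored runs.

    ``times`` holds the 1-based first-alarm index per run, ``NaN`` when no
    signal occurred within the volume ``n``.
    """

    times: np.ndarray = field(repr=False)
    n: int

    @property
    def signalled(self) -> np.ndarray:
        return ~np.isnan(self.times)

    @property
    def signal_fraction(self) -> float:
        return float(np.mean(self.signalled))

    def summary(self) -> dict[str, float]:
        hit = self.times[self.signalled]
        return {
            "n_runs": float(self.times.size),
            "signal_fraction": self.signal_fraction,
            "median_time_to_signal": float(np.median(hit)) if hit.size else float("nan"),
            "mean_time_to_signal": float(np.mean(hit)) if hit.size else float("nan"),
        }


@dataclass(frozen=True)
class SignalRateEstimate:
    """Proportion of simulated runs signalling within ``n`` observations."""

    rate: float
    n_runs: int
    scenario: Literal["in_control", "out_of_control"]
    delta_true: float
    run_lengths: RunLengthSample = field(repr=False)

    @property
    def mc_stderr(self) -> float:
        """Normal-approximation Monte-Carlo standard error of the rate."""
        return float(np.sqrt(self.rate * (1.0 - self.rate) / self.n_runs))


def estimate_signal_rate(
    indicator: Indicator | RiskPopulation,
    n: int,
    delta_design: float,
    h: float,
    delta_true: float = 1.0,
    n_runs: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> SignalRateEstimate:
    """Simulate monitored runs and estimate the signal rate against limit ``h``.

    The chart's weights stay at ``delta_design`` while the data-generating
    odds are multiplied by ``delta_true`` (1 = in control).  For a
    risk-adjusted indicator, risks are resampled with replacement from the
    population per patient and the chart weights use the unshifted
    (Phase-I) scores.
    """
    if isinstance(indicator, RiskPopulation):
        indicator = indicator.to_indicator()
    if h < 0.0:
        raise ValueError("control limit h must be nonnegative")
    rng = np.random.default_rng(seed)
    weights = _shifted_weights(
        indicator, int(n), float(delta_design), float(delta_true), int(n_runs), rng
    )
    stats = _batch_statistics(weights)
    hit = stats >= h - LIMIT_TOL
    signalled = hit.any(axis=1)
    times = np.where(signalled, hit.argmax(axis=1) + 1.0, np.nan)
    scenario = "in_control" if delta_true == 1.0 else "out_of_control"
    return SignalRateEstimate(
        rate=float(np.mean(signalled)),
        n_runs=int(n_runs),
        scenario=scenario,
        delta_true=float(delta_true),
        run_lengths=RunLengthSample(times=times, n=int(n)),
    )


def power_grid(
    indicator: Indicator | RiskPopulation,
    volumes: Iterable[int],
    alphas: Iterable[float],
    deltas: Iterable[float],
    n_runs_limit: int = 100_000,
    n_runs_eval: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulation study over a (volume, alpha, delta) grid.

    For each cell a control limit is simulated, then in-control
    (``delta_true = 1``) and out-of-control (``delta_true = delta``) signal
    rates are estimated.  Returns a tidy frame with one row per cell and
    scenario, suitable for plotting signal rates against the grid.
    """
    if isinstance(indicator, RiskPopulation):
        indicator = indicator.to_indicator()
    rng = np.random.default_rng(seed)
    rows = []
    for n in volumes:
        for alpha in alphas:
            for delta in deltas:
                limit = simulate_control_limit(
                    indicator, n, delta, alpha, n_runs=n_runs_limit, seed=rng
                )
                for delta_true in (1.0, float(delta)):
                    est = estimate_signal_rate(
                        indicator,
                        n,
                        delta,
                        limit.h,
                        delta_true=delta_true,
                        n_runs=n_runs_eval,
                        seed=rng,
                    )
                    rows.append(
                        {
                            "indicator": indicator.id,
                            "n": int(n),
                            "alpha": float(alpha),
                            "delta": float(delta),
                            "h": limit.h,
                            "achieved_alpha": limit.achieved_alpha,
                            "degenerate": limit.degenerate,
                            "scenario": est.scenario,
                            "delta_true": est.delta_true,
                            "signal_rate": est.rate,
                            "mc_stderr": est.mc_stderr,
                            "n_runs": est.n_runs,
                        }
                    )
    return pd.DataFrame(rows)
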