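"""Model-style front end: :class:`CusumChart` and :class:`CusumChartResults`.

A :class:`CusumChart` bundles an indicator (Phase-I estimate), a volume and
a chart design (detection level, target false-alarm probability).  Calling
:meth:`CusumChart.fit` calibrates the control limit — by Monte-Carlo
simulation, or exact enumeration at small volumes — and returns a
:class:`CusumChartResults` carrying the limit, its achieved false-alarm
probability and Monte-Carlo uncertainty, with methods to monitor new
outcome sequences, evaluate signal rates, and plot.

    >>> chart = CusumChart(CrudeIndicator("femur_fracture_delay", c0=0.1921),
    ...                    n=105, delta=2.0, alpha=0.05)
    >>> res = chart.fit(seed=7)
    >>> run = res.monitor(outcomes)          # doctest: +SKIP
    >>> print(res.summary())                 # doctest: +SKIP
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .engine import CusumRun, run_monitored, time_to_signal
from .evaluation import SignalRateEstimate, estimate_signal_rate
from .indicators import (
    CrudeIndicator,
    RiskAdjustedIndicator,
    estimate_phase1,
    ra_weight_pairs,
    st_weights,
)
from .limits import (
    ENUMERATION_MAX_N,
    ControlLimitResult,
    exact_control_limit_table,
    select_exact_limit,
    simulate_control_limit,
)
from .simulate import RiskPopulation

__all__ = ["CusumChart", "CusumChartResults"]


class CusumChart:
    """Specification of a Bernoulli CUSUM monitoring chart.

    Parameters
    ----------
    indicator
        A :class:`CrudeIndicator`, :class:`RiskAdjustedIndicator` or
        :class:`RiskPopulation` (converted to a risk-adjusted indicator).
    n
        Hospital volume: the number of observations in one monitoring
        period, which is the horizon of the false-alarm probability.
    delta
        Detection level — the odds-ratio multiplier the chart is tuned to
        detect (> 1 deterioration, < 1 improvement).
    alpha
        Target probability of at least one false alarm within ``n``
        in-control observations.
    """

    def __init__(
        self,
        indicator: CrudeIndicator | RiskAdjustedIndicator | RiskPopulation,
        n: int,
        delta: float = 2.0,
        alpha: float = 0.05,
    ) -> None:
        if isinstance(indicator, RiskPopulation):
            indicator = indicator.to_indicator()
        self.indicator = indicator
        self.n = int(n)
        self.delta = float(delta)
        self.alpha = float(alpha)

    @classmethod
    def from_dataframe(
        cls,
        phase1: pd.DataFrame,
        n: int | None = None,
        delta: float = 2.0,
        alpha: float = 0.05,
        outcome_col: str = "y",
        risk_col: str = "p",
        id: str = "indicator",
    ) -> "CusumChart":
        """Build the chart from Phase-I per-patient data.

        The pooled failure rate of ``outcome_col`` becomes ``c0``; if
        ``risk_col`` is present its scores become the case-mix population
        (risk-adjusted pathway).  ``n`` defaults to the Phase-I volume.
        """
        scores = phase1[risk_col].to_numpy() if risk_col in phase1.columns else None
        indicator = estimate_phase1(phase1[outcome_col].to_numpy(), scores, id=id)
        return cls(indicator, n=n if n is not None else len(phase1), delta=delta, alpha=alpha)

    def fit(
        self,
        method: Literal["auto", "simulated", "exact"] = "simulated",
        n_runs: int = 100_000,
        seed: int | np.random.Generator | None = None,
    ) -> "CusumChartResults":
        """Calibrate the control limit to the target false-alarm probability.

        ``method="exact"`` enumerates all outcome paths (crude charts,
        ``n <= 20``); ``"auto"`` picks exact where available.  The
        simulated path runs ``n_runs`` in-control CUSUM runs.
        """
        exact_ok = isinstance(self.indicator, CrudeIndicator) and self.n <= ENUMERATION_MAX_N
        if method == "auto":
            method = "exact" if exact_ok else "simulated"
        if method == "exact":
            if not exact_ok:
                raise ValueError(
                    "exact fit requires a crude indicator and "
                    f"n <= {ENUMERATION_MAX_N} (got n={self.n})"
                )
            table = exact_control_limit_table(self.indicator, self.n, self.delta)
            limit = select_exact_limit(
                table, self.alpha, n=self.n,
                indicator_id=self.indicator.id, delta=self.delta,
            )
        elif method == "simulated":
            limit = simulate_control_limit(
                self.indicator, self.n, self.delta, self.alpha, n_runs=n_runs, seed=seed
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        return CusumChartResults(self, limit)


class CusumChartResults:
    """Fitted chart: the calibrated control limit and everything it implies."""

    def __init__(self, model: CusumChart, limit: ControlLimitResult) -> None:
        self.model = model
        self.limit = limit

    # -- estimates -----------------------------------------------------
    @property
    def h(self) -> float:
        """The control limit."""
        return self.limit.h

    @property
    def achieved_alpha(self) -> float:
        """False-alarm probability actually achieved by ``h`` (simulated or exact)."""
        return self.limit.achieved_alpha

    @property
    def alpha_stderr(self) -> float:
        """Monte-Carlo standard error of ``achieved_alpha`` (0 for exact fits)."""
        if self.limit.method == "exact" or not self.limit.n_runs:
            return 0.0
        a = self.achieved_alpha
        return float(np.sqrt(a * (1.0 - a) / self.limit.n_runs))

    @property
    def degenerate(self) -> bool:
        return self.limit.degenerate

    def weights(self, risk_scores: Sequence[float] | None = None):
        """Chart weights: a :class:`WeightPair` (crude) or per-patient pairs (RA)."""
        if isinstance(self.model.indicator, CrudeIndicator):
            return st_weights(self.model.indicator.c0, self.model.delta)
        if risk_scores is None:
            raise ValueError("risk-adjusted chart: pass the patients' risk scores")
        return ra_weight_pairs(np.asarray(risk_scores, dtype=float), self.model.delta)

    # -- monitoring ----------------------------------------------------
    def monitor(
        self,
        outcomes: Sequence[int] | np.ndarray,
        risk_scores: Sequence[float] | None = None,
        reset_policy: str = "to_zero",
        reset_value: float = 0.0,
    ) -> CusumRun:
        """Run Phase-II outcomes through the monitored chart."""
        return run_monitored(
            outcomes,
            self.weights(risk_scores),
            self.h,
            reset_policy=reset_policy,
            reset_value=reset_value,
        )

    def signal_rate(
        self,
        delta_true: float = 1.0,
        n_runs: int = 2000,
        seed: int | np.random.Generator | None = None,
    ) -> SignalRateEstimate:
        """Simulated probability of signalling within ``n`` at a true odds shift."""
        return estimate_signal_rate(
            self.model.indicator, self.model.n, self.model.delta, self.h,
            delta_true=delta_true, n_runs=n_runs, seed=seed,
        )

    def plot(self, run: CusumRun | None = None, ax=None, **kwargs):
        """Plot a monitored run against the control limit."""
        from .plotting import plot_run

        if run is None:
            raise ValueError("pass the CusumRun returned by .monitor()")
        return plot_run(run, ax=ax, **kwargs)

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        ind = self.model.indicator
        kind = "risk-adjusted (RA)" if ind.risk_adjusted else "crude (ST)"
        lines = [
            "Bernoulli CUSUM chart",
            "=" * 58,
            f"{'indicator':<28}{ind.id}",
            f"{'chart type':<28}{kind}",
        ]
        if isinstance(ind, CrudeIndicator):
            lines.append(f"{'baseline failure prob c0':<28}{ind.c0:.4f}")
        else:
            lines.append(f"{'case-mix population size':<28}{ind.risk_scores.size}")
            lines.append(f"{'mean Phase-I risk':<28}{ind.mean_risk:.4f}")
        lines += [
            f"{'volume n':<28}{self.model.n}",
            f"{'detection level delta':<28}{self.model.delta:g}",
            f"{'target false-alarm prob':<28}{self.model.alpha:g}",
            "-" * 58,
            f"{'control limit h':<28}{self.h:.5f}",
            f"{'achieved false-alarm prob':<28}{self.achieved_alpha:.5f}"
            + (f"  (MC se {self.alpha_stderr:.5f})" if self.limit.method == "simulated" else "  (exact)"),
            f"{'method':<28}{self.limit.method}"
            + (f", {self.limit.n_runs} runs" if self.limit.n_runs else ""),
        ]
        if self.degenerate:
            lines.append(
                "warning: degenerate limit — discrete support leaves no "
                "attainable limit near the target"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def monitor_summary(self, run: CusumRun) -> dict:
        """Alarm summary of a monitored run (for reports)."""
        ts = time_to_signal(run)
        return {
            "n": run.n,
            "h": self.h,
            "n_alarms": int(run.alarms.size),
            "alarm_times": run.alarms.tolist(),
            "time_to_signal": ts,
            "final_cusum": run.final_statistic,
        }
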