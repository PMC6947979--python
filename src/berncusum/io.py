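"""File formats and the Phase-I/Phase-II monitoring pipeline.

Performance data is exchanged as tidy CSV with one row per patient:
``hospital_id``, ``y`` (0 success / 1 adverse event), optional ``t``
(sequence position; row order within hospital otherwise) and optional
``p`` (per-patient risk score), which switches the risk-adjusted pathway
on.

:func:`run_pipeline` reproduces the annual monitoring workflow: a
historical period (Phase I) estimates each hospital's baseline failure
probability or case-mix population, a control limit is simulated at the
hospital's current (Phase-II) volume, and the Phase-II outcomes are run
through the monitored chart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .engine import run_monitored
from .indicators import estimate_phase1, ra_weight_pairs, st_weights
from .limits import simulate_control_limit

__all__ = [
    "ChartReport",
    "read_performance_csv",
    "write_performance_csv",
    "load_config",
    "run_pipeline",
]

logger = logging.getLogger("berncusum")

_REQUIRED = ("hospital_id", "y")


def _validate(frame: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise ValueError(f"{source}: missing required column(s) {missing}")
    bad_y = ~frame["y"].isin((0, 1))
    if bad_y.any():
        row = int(frame.index[bad_y][0])
        raise ValueError(f"{source}: non-binary outcome y={frame['y'].iloc[row]!r} at row {row}")
    if "t" not in frame.columns:
        frame = frame.copy()
        frame["t"] = frame.groupby("hospital_id").cumcount() + 1
    if "p" in frame.columns:
        p = frame["p"].to_numpy(dtype=float)
        bad_p = ~((p > 0.0) & (p < 1.0))
        if bad_p.any():
            row = int(np.nonzero(bad_p)[0][0])
            raise ValueError(
                f"{source}: risk score p={p[row]!r} outside (0, 1) at row {row}"
            )
    frame = frame.sort_values(["hospital_id", "t"], kind="stable").reset_index(drop=True)
    dup = frame.duplicated(subset=["hospital_id", "t"])
    if dup.any():
        key = frame.loc[dup.idxmax(), ["hospital_id", "t"]].tolist()
        raise ValueError(f"{source}: duplicate (hospital_id, t) = {tuple(key)}")
    frame["y"] = frame["y"].astype(np.int8)
    frame["t"] = frame["t"].astype(np.int64)
    return frame


def read_performance_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-patient performance CSV."""
    frame = pd.read_csv(path)
    return _validate(frame, str(path))


def write_performance_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a performance dataset; round-trips through :func:`read_performance_csv`."""
    cols = [c for c in ("hospital_id", "t", "y", "p") if c in frame.columns]
    frame.to_csv(path, columns=cols, index=False)


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


@dataclass
class ChartReport:
    """Pipeline output: per-hospital summary plus per-observation detail.

    ``summary`` has one row per monitored hospital (volume, limit, achieved
    alpha, alarm count and times, final statistic); ``details`` stacks the
    per-observation chart tables.
    """

    summary: pd.DataFrame
    details: pd.DataFrame
    config: dict[str, Any]

    def __post_init__(self) -> None:
        for _, row in self.summary.iterrows():
            if row["n_alarms"] != len(row["alarm_times"]):
                raise ValueError("alarm count inconsistent with alarm time list")


def run_pipeline(
    config: dict[str, Any] | str | Path,
    phase1: pd.DataFrame | None = None,
    phase2: pd.DataFrame | None = None,
) -> ChartReport:
    """Run the two-phase monitoring workflow for every eligible hospital.

    ``config`` keys (or a YAML file of them): ``phase1``/``phase2`` (CSV
    paths, unless frames are passed directly), ``alpha`` (target
    false-alarm probability, default 0.05), ``delta`` (detection level,
    default 2), ``seed``, ``n_runs`` (limit simulation size, default
    100000), ``reset`` (``to_zero``/``none``, default ``to_zero``),
    ``min_obs`` (eligibility threshold per phase, default 2).

    Hospitals present in Phase II but absent (or ineligible) in Phase I
    are excluded with a logged warning.  Control limits are simulated at
    each hospital's own Phase-II volume; a volume change of more than 20%
    against Phase I is logged, since the limit may then be miscalibrated
    for the period actually monitored.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    if phase1 is None:
        phase1 = read_performance_csv(config["phase1"])
    else:
        phase1 = _validate(phase1, "phase1")
    if phase2 is None:
        phase2 = read_performance_csv(config["phase2"])
    else:
        phase2 = _validate(phase2, "phase2")

    alpha = float(config.get("alpha", 0.05))
    delta = float(config.get("delta", 2.0))
    n_runs = int(config.get("n_runs", 100_000))
    reset = str(config.get("reset", "to_zero"))
    min_obs = int(config.get("min_obs", 2))
    rng = np.random.default_rng(config.get("seed"))
    risk_adjusted = "p" in phase1.columns and "p" in phase2.columns

    phase1_groups = dict(tuple(phase1.groupby("hospital_id")))
    rows, details = [], []
    for hospital, g2 in phase2.groupby("hospital_id"):
        g1 = phase1_groups.get(hospital)
        if g1 is None:
            logger.warning("hospital %s absent from Phase I; excluded", hospital)
            continue
        if len(g1) < min_obs or len(g2) < min_obs:
            logger.warning(
                "hospital %s below eligibility threshold (%d Phase-I / %d Phase-II obs)",
                hospital, len(g1), len(g2),
            )
            continue
        n = len(g2)
        if abs(n - len(g1)) > 0.2 * len(g1):
            logger.warning(
                "hospital %s volume changed by >20%% between phases (%d -> %d); "
                "the simulated limit targets the Phase-II volume", hospital, len(g1), n,
            )
        try:
            indicator = estimate_phase1(
                g1["y"].to_numpy(),
                g1["p"].to_numpy() if risk_adjusted else None,
                id=str(hospital),
            )
        except ValueError as exc:
            logger.warning("hospital %s: Phase-I estimation failed (%s); excluded", hospital, exc)
            continue
        limit = simulate_control_limit(indicator, n, delta, alpha, n_runs=n_runs, seed=rng)
        if risk_adjusted:
            weights = ra_weight_pairs(g2["p"].to_numpy(), delta)
        else:
            weights = st_weights(indicator.c0, delta)
        run = run_monitored(g2["y"].to_numpy(), weights, limit.h, reset_policy=reset)
        logger.info(
            "hospital %s: n=%d h=%.4f achieved_alpha=%.4f alarms=%d%s",
            hospital, n, limit.h, limit.achieved_alpha, run.alarms.size,
            " [degenerate limit]" if limit.degenerate else "",
        )
        rows.append(
            {
                "hospital_id": hospital,
                "n": n,
                "h": limit.h,
                "achieved_alpha": limit.achieved_alpha,
                "degenerate_limit": limit.degenerate,
                "n_alarms": int(run.alarms.size),
                "alarm_times": run.alarms.tolist(),
                "final_cusum": run.final_statistic,
            }
        )
        detail = run.to_frame()
        detail.insert(0, "hospital_id", hospital)
        if risk_adjusted:
            detail["p"] = g2["p"].to_numpy()
        details.append(detail)

    summary = pd.DataFrame(
        rows,
        columns=[
            "hospital_id", "n", "h", "achieved_alpha", "degenerate_limit",
            "n_alarms", "alarm_times", "final_cusum",
        ],
    )
    detail_frame = (
        pd.concat(details, ignore_index=True)
        if details
        else pd.DataFrame(columns=["hospital_id", "t", "y", "weight", "cusum", "alarm"])
    )
    return ChartReport(summary=summary, details=detail_frame, config=dict(config))
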