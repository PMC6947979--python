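"""Chart plots: CUSUM trajectory with control limit and alarm markers."""

from __future__ import annotations

import numpy as np

from .engine import CusumRun

__all__ = ["plot_run"]


def plot_run(run: CusumRun, ax=None, title: str | None = None):
    """Plot a CUSUM trajectory; adverse events and alarms are marked.

    Returns the matplotlib axes.  The control limit, when present, is the
    horizontal dashed line.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.2))
    t = np.arange(run.n + 1)
    ax.step(t, run.statistics, where="post", lw=1.2, color="#1f4e79")
    failures = np.nonzero(run.outcomes == 1)[0] + 1
    ax.plot(failures, run.statistics[failures], "o", ms=4, color="#b03030",
            label="adverse event")
    if run.limit is not None:
        ax.axhline(run.limit, ls="--", color="black", lw=1, label=f"h = {run.limit:.3g}")
        if run.alarms.size:
            ax.plot(run.alarms, run.statistics[run.alarms], "x", ms=9, mew=2,
                    color="#b03030", label="alarm")
    ax.set_xlabel("observation t")
    ax.set_ylabel(r"CUSUM statistic $C_t$")
    ax.set_ylim(bottom=0)
    if title:
        ax.set_title(title)
    ax.legend(loc="upper left", frameon=False, fontsize=8)
    return ax
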