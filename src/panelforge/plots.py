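"""Plotting helpers for evaluation outputs (matplotlib, Agg-safe)."""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_roc", "plot_kaplan_meier", "plot_forest"]


def plot_roc(roc_points: pd.DataFrame, auc: Optional[float] = None,
             label: str = "", ax=None):
    """ROC curve from (threshold, tpr, fpr) points."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    name = f"{label} (AUC {auc:.3f})" if auc is not None else label
    ax.plot(roc_points["fpr"], roc_points["tpr"], drawstyle="steps-post",
            label=name or None)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    if name:
        ax.legend(loc="lower right", frameon=False)
    return ax


def plot_kaplan_meier(curves: Dict[str, pd.DataFrame], ax=None):
    """Step survival curves per group with censoring ticks."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for grp, tab in sorted(curves.items()):
        ax.step(tab["time"], tab["survival"], where="post", label=grp)
        cens = tab[tab["censored"] > 0]
        ax.plot(cens["time"], cens["survival"], "|", ms=6, c=ax.lines[-1].get_color())
    ax.set_xlabel("years")
    ax.set_ylabel("progression-free fraction")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    return ax


def plot_forest(rows: Sequence[dict], ax=None):
    """Forest plot of hazard ratios: rows with signature, hr, ci_low,
    ci_high."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.4 * max(4, len(rows))))
    ys = range(len(rows))
    for y, r in zip(ys, rows):
        ax.plot([r["ci_low"], r["ci_high"]], [y, y], c="k", lw=1)
        ax.plot(r["hr"], y, "s", c="k", ms=4)
    ax.axvline(1.0, ls="--", c="grey", lw=0.8)
    ax.set_yticks(list(ys))
    ax.set_yticklabels([r["signature"] for r in rows])
    ax.set_xscale("log")
    ax.set_xlabel("hazard ratio (high vs low)")
    ax.invert_yaxis()
    return ax
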