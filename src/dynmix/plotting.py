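"""Diagnostic plots for traces, learning curves and grid results."""

from __future__ import annotations

import numpy as np


def plot_learning_curve(curves: dict, ax=None, fraction: float = 0.8):
    """Plot RI vs within-clinic prediction index for one or more models.

    ``curves`` maps a label to a :class:`~dynmix.evaluate.LearningCurve`.
    Vertical lines mark the index at which ``fraction`` of the total gains
    have been attained.
    """
    import matplotlib.pyplot as plt

    from .evaluate import gains_threshold

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    styles = ["-", "--", ":", "-."]
    for (label, curve), ls in zip(curves.items(), styles * 4):
        ax.plot(curve.index, curve.ri, ls, label=label)
        j_star, degenerate = gains_threshold(curve, fraction)
        if not degenerate:
            ax.axvline(j_star, linestyle=ls, alpha=0.4)
    ax.set_xlabel("prediction index $j$ within clinic")
    ax.set_ylabel("relative improvement in MAE")
    ax.set_ylim(top=1.05)
    ax.legend()
    return ax


def plot_ri_distributions(metrics, by: str = "model", ax=None):
    """Violin-style summary of replicate RI values from a tidy metrics
    table (as produced by the experiment runner), grouped by ``by``."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    groups = list(metrics.groupby(by)["ri"])
    ax.violinplot([np.asarray(v) for _, v in groups], showmeans=True)
    ax.set_xticks(np.arange(1, len(groups) + 1), [str(k) for k, _ in groups])
    ax.set_ylabel("relative improvement in MAE")
    return ax
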