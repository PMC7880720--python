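"""Bland-Altman and mountain (folded-ECDF) plots."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evaluation import bland_altman, ecdp_stats

__all__ = ["bland_altman_plot", "mountain_plot"]


def bland_altman_plot(reference, measured, ax=None, label=None):
    """Difference-vs-mean scatter with mean line and limits of agreement."""
    reference = np.asarray(reference, dtype=float).ravel()
    measured = np.asarray(measured, dtype=float).ravel()
    report = bland_altman(reference, measured)
    means = (reference + measured) / 2.0
    diffs = measured - reference
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=12, alpha=0.6, label=label)
    ax.axhline(report.mean_diff, color="tab:blue", lw=1.5)
    for limit in (report.loa_lower, report.loa_upper):
        ax.axhline(limit, color="tab:red", ls="--", lw=1.2)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (measured - reference)")
    ax.set_title(
        f"mean {report.mean_diff:.3f}, LoA "
        f"[{report.loa_lower:.3f}, {report.loa_upper:.3f}], "
        f"outside {report.n_outside}/{report.n}"
    )
    return ax


def mountain_plot(differences, ax=None, label=None):
    """Folded empirical CDF of differences (peaks at the median)."""
    summary = ecdp_stats(differences)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(summary.folded_curve[:, 0], summary.folded_curve[:, 1], label=label)
    ax.axvline(summary.median, color="grey", ls=":", lw=1)
    ax.set_xlabel("difference")
    ax.set_ylabel("folded cumulative fraction")
    ax.set_ylim(0, 0.55)
    return ax
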