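"""Figure analogues of the study's plots (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .match_phase import Kernel
from .detection import kde_scores
from .control_phase import potentiation_sigmoid

__all__ = [
    "plot_kernel",
    "plot_kernel_fit_scatter",
    "plot_offset_curve",
    "plot_score_kdes",
    "plot_roc",
    "plot_sigmoid",
    "plot_control_summary",
]


def _save(fig, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_kernel(kernel: Kernel, path):
    """Fitted temporal kernel with its fixed decay envelope."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    eff = kernel.values * kernel.envelope
    ax.plot(kernel.grid, eff, lw=1.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("t_post - t_pre (ms)")
    ax.set_ylabel("K (score units)")
    ax.set_title("Fitted temporal kernel")
    _save(fig, path)


def plot_kernel_fit_scatter(predicted, observed, r2, path, n_show=1000):
    fig, ax = plt.subplots(figsize=(4, 4))
    idx = np.random.default_rng(0).permutation(len(predicted))[:n_show]
    ax.plot(np.asarray(predicted)[idx], np.asarray(observed)[idx], ".", ms=3, alpha=0.4)
    lim = max(np.max(predicted), np.max(observed))
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("kernel model")
    ax.set_ylabel("simulated calcium integral")
    ax.set_title(f"Held-out fit, r$^2$={r2:.2f}")
    _save(fig, path)


def plot_offset_curve(sweep, path):
    """Mean detector score vs. pre-before-BAP offset."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.errorbar(sweep["offset_ms"], sweep["mean_score"], yerr=sweep["se_score"], lw=1.2)
    peak = sweep["offset_ms"].iloc[int(np.argmax(sweep["mean_score"]))]
    ax.axvline(peak, color="crimson", ls=":", label=f"max at {peak:g} ms")
    ax.set_xlabel("pre-spike lead before BAP (ms)")
    ax.set_ylabel("mean detector score")
    ax.legend(frameon=False)
    _save(fig, path)


def plot_score_kdes(matched_by_window, null_scores_by_window, thresholds, path):
    """Normalized-score densities for matched vs random trains per window."""
    fig, axes = plt.subplots(1, len(matched_by_window), figsize=(10, 3), sharey=False)
    axes = np.atleast_1d(axes)
    for ax, w in zip(axes, matched_by_window):
        thr = thresholds[w]
        for scores, color, lab in (
            (matched_by_window[w], "tab:blue", "matched"),
            (null_scores_by_window[w], "tab:red", "random"),
        ):
            if len(scores) >= 10 and np.var(scores) > 0:
                g, d = kde_scores(np.asarray(scores) / thr)
                ax.plot(g, d, color=color, label=lab)
        ax.axvline(1.0, color="k", ls=":")
        ax.set_title(f"{w} s window")
        ax.set_xlabel("normalized score")
    axes[0].set_ylabel("density")
    axes[0].legend(frameon=False)
    _save(fig, path)


def plot_roc(rocs, path):
    """ROC curves (family-wise FPR) for several conditions."""
    fig, ax = plt.subplots(figsize=(4, 4))
    for label, roc in rocs.items():
        ax.plot(roc[:, 0], roc[:, 1], label=str(label))
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="no discrimination")
    ax.set_xlabel("family-wise false-positive rate")
    ax.set_ylabel("true-positive rate")
    ax.legend(frameon=False, fontsize=8)
    _save(fig, path)


def plot_sigmoid(path, center=None, width=None):
    fig, ax = plt.subplots(figsize=(4, 3))
    s = np.linspace(0, 1.5, 400)
    kw = {}
    if center is not None:
        kw["center"] = center
    if width is not None:
        kw["width"] = width
    ax.plot(s, potentiation_sigmoid(s, **kw))
    ax.axvline(1.0, color="k", ls=":", label="threshold")
    ax.set_xlabel("normalized calcium integral")
    ax.set_ylabel("EPSP potentiation factor")
    ax.legend(frameon=False)
    _save(fig, path)


def plot_control_summary(reports_by_window, path):
    """Successful vs spurious percentages per match window (means)."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ws = sorted(reports_by_window)
    succ = [100 * np.mean([r.pct_successful for r in reports_by_window[w]]) for w in ws]
    spur = [100 * np.mean([r.pct_spurious for r in reports_by_window[w]]) for w in ws]
    x = np.arange(len(ws))
    ax.bar(x - 0.15, succ, width=0.3, color="tab:blue", label="% successful")
    ax.bar(x + 0.15, spur, width=0.3, color="tab:red", label="% spurious")
    ax.set_xticks(x, [f"{w} s" for w in ws])
    ax.set_ylabel("percent of spikes")
    ax.legend(frameon=False)
    _save(fig, path)
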