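"""Threshold calibration, detection rates, KDE and ROC analyses.

The potentiation threshold is calibrated on null-only simulations (all
axons random): the threshold is the empirical ``target`` quantile (default
0.90) of the per-run *maximum* score over the 149 null spine groups, so
that a run rejects every null axon with the target family-wise
probability.  Raw scores divided by this threshold are "normalized": 1 is
the threshold for potentiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "ThresholdCalibration",
    "DetectionReport",
    "calibrate_threshold",
    "evaluate_detection",
    "kde_scores",
    "roc_curve",
]


@dataclass(frozen=True)
class ThresholdCalibration:
    """A calibrated potentiation threshold.

    The threshold is the ``target_familywise_reject`` empirical quantile
    (linear interpolation between order statistics) of the per-run maximum
    null score.
    """

    threshold: float
    target_familywise_reject: float
    n_null_sims: int
    window: float
    quantile_method: str = "linear"

    def normalize(self, raw: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(raw, dtype=float) / self.threshold if np.ndim(raw) \
            else float(raw) / self.threshold


def calibrate_threshold(
    null_runs: list[np.ndarray] | np.ndarray,
    target: float = 0.9,
    window: float = 1.0,
    strict: bool = True,
) -> ThresholdCalibration:
    """Calibrate the potentiation threshold from null-only runs.

    Parameters
    ----------
    null_runs
        One score list per run, each containing only non-matched spine
        groups (149 by default), or a pre-computed 1-D array of per-run
        maxima.
    target
        Desired family-wise rejection probability (default 0.9: all null
        axons stay below threshold 90% of the time).
    strict
        Fewer than 50 runs raise an error (the quantile estimate would be
        dominated by calibration variance); with ``strict=False`` a small
        calibration set is accepted.
    """
    if not 0 < target <= 1:
        raise ValueError("target must be in (0, 1]")
    arr = [np.asarray(r, dtype=float) for r in null_runs]
    if any(a.ndim != 0 and a.size == 0 for a in arr):
        raise ValueError("each null run must contain at least one score")
    maxima = np.array([a.max() if a.ndim else float(a) for a in arr])
    if maxima.size < 50 and strict:
        raise ValueError(
            f"only {maxima.size} calibration runs; need >= 50 (set strict=False "
            "to accept the extra calibration variance)"
        )
    thr = float(np.quantile(maxima, target, method="linear"))
    if thr <= 0:
        raise ValueError("calibrated threshold is not positive; null scores degenerate")
    return ThresholdCalibration(thr, target, int(maxima.size), window)


@dataclass(frozen=True)
class DetectionReport:
    """True-positive and family-wise false-positive rates plus a ROC curve."""

    tpr: float
    familywise_fpr: float
    roc: np.ndarray          # (n, 2) columns (fpr, tpr), threshold swept
    window: float
    jitter_sd: float = 0.0   # ms
    threshold: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "tpr": self.tpr,
            "familywise_fpr": self.familywise_fpr,
            "window": self.window,
            "jitter_sd_ms": self.jitter_sd,
            "threshold": self.threshold,
            "roc": [[float(f), float(t)] for f, t in self.roc],
        }


def roc_curve(matched_scores: np.ndarray, null_run_maxima: np.ndarray) -> np.ndarray:
    """ROC by sweeping the threshold over all observed scores.

    The false-positive rate is family-wise: the probability that *any*
    null axon of a run crosses the threshold, i.e. that the run's maximum
    does.  Output rows run from (0, 0) to (1, 1) and are monotone in both
    coordinates.
    """
    m = np.sort(np.asarray(matched_scores, dtype=float))
    x = np.sort(np.asarray(null_run_maxima, dtype=float))
    thresholds = np.unique(np.concatenate([m, x]))[::-1]
    pts = [(0.0, 0.0)]
    for thr in thresholds:
        tpr = float(np.mean(m > thr))
        fpr = float(np.mean(x > thr))
        pts.append((fpr, tpr))
    pts.append((1.0, 1.0))
    roc = np.array(pts)
    order = np.lexsort((roc[:, 1], roc[:, 0]))
    return np.unique(roc[order], axis=0)


def evaluate_detection(
    matched_scores: np.ndarray,
    null_run_maxima: np.ndarray,
    threshold: float | ThresholdCalibration,
    window: float = 1.0,
    jitter_sd: float = 0.0,
) -> DetectionReport:
    """Detection performance at a fixed threshold, plus the full ROC.

    ``matched_scores`` (one per matched run) and ``null_run_maxima`` (one
    per null run) must come from runs independent of the calibration set.
    """
    thr = threshold.threshold if isinstance(threshold, ThresholdCalibration) \
        else float(threshold)
    m = np.asarray(matched_scores, dtype=float)
    x = np.asarray(null_run_maxima, dtype=float)
    return DetectionReport(
        tpr=float(np.mean(m > thr)),
        familywise_fpr=float(np.mean(x > thr)),
        roc=roc_curve(m, x),
        window=window,
        jitter_sd=jitter_sd,
        threshold=thr,
    )


def kde_scores(
    scores: np.ndarray,
    bandwidth: str | float = "scott",
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density estimate of a score distribution.

    Returns ``(grid, density)`` with the density normalized to integrate
    to 1 over the real line (trapezoidal check over the returned grid will
    be slightly below 1 if the grid clips the tails; the default grid pads
    by 3 bandwidths).  Degenerate (zero-variance) samples raise.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 10:
        raise ValueError("need at least 10 scores for a density estimate")
    if np.var(s) == 0:
        raise ValueError("scores are degenerate (zero variance)")
    kde = gaussian_kde(s, bw_method=bandwidth)
    if grid is None:
        bw = kde.covariance_factor() * s.std()
        grid = np.linspace(s.min() - 3 * bw, s.max() + 3 * bw, 512)
    return grid, kde(grid)
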