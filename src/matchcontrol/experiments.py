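"""High-level experiment drivers: calibration batches, TPR tables, pipelines.

These functions assemble the per-module operations into the study's
analyses: batches of null-only runs for threshold calibration, batches of
matched runs for true-positive rates, the jitter study, and the full
match-to-control pipeline.  All randomness flows from one master seed
through named :class:`numpy.random.SeedSequence` streams, so every batch
is reproducible and disjoint seeds are guaranteed between calibration and
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spike_trains import (
    SpikeTrain,
    TrainEnsemble,
    sample_poisson_refractory,
    make_matched_train,
)
from .dendrite import Geometry, SpineParams, build_geometry, simulate_scores
from .detection import (
    ThresholdCalibration,
    calibrate_threshold,
    evaluate_detection,
)
from .control_phase import (
    ControlParams,
    ControlReport,
    simulate_control,
    state_from_score,
)

__all__ = [
    "StudyDesign",
    "null_run_maxima",
    "matched_run_scores",
    "calibrate",
    "detection_study",
    "control_study",
]

# stream tags (SeedSequence entropy words) for the named sub-streams
_TAG_NULL, _TAG_MATCHED, _TAG_NOISE, _TAG_JITTER, _TAG_CONTROL = range(101, 106)


@dataclass(frozen=True)
class StudyDesign:
    """The stimulus conditions shared by all experiments."""

    rate: float = 6.0          # Hz, nominal (realized) Poisson rate
    refractory: float = 0.05   # s dead time of the Poisson sampler
    n_axons: int = 150         # keys per neuron
    lead: float = 0.007        # s, matched pre spike leads BAP arrival
    params: SpineParams = field(default_factory=SpineParams)
    geometry: Geometry | None = None

    def geom(self) -> Geometry:
        return self.geometry or build_geometry(self.n_axons, 10)


def null_run_maxima(
    n_runs: int,
    window: float,
    design: StudyDesign = StudyDesign(),
    seed: int = 0,
    n_null: int | None = None,
) -> np.ndarray:
    """Per-run maximum detector score over null-only spine groups.

    Each run draws a fresh query train and ``n_null`` (default
    ``n_axons - 1 = 149``) independent random key trains, scores every
    group and keeps the maximum -- the family-wise statistic the threshold
    is calibrated on.
    """
    if n_null is None:
        n_null = design.n_axons - 1
    geom = design.geom()
    shifts = np.asarray(geom.latencies[1 : n_null + 1], dtype=float) * 1e-3
    maxima = np.empty(n_runs)
    for r in range(n_runs):
        ss = np.random.SeedSequence([seed, _TAG_NULL, r])
        post_s, trains_s, noise_s = ss.spawn(3)
        post = sample_poisson_refractory(
            design.rate, design.refractory, window, np.random.default_rng(post_s)
        )
        nulls = [
            sample_poisson_refractory(
                design.rate, design.refractory, window, np.random.default_rng(s)
            ).times
            for s in trains_s.spawn(n_null)
        ]
        scores = simulate_scores(
            nulls, [post.times], window, design.params, seed=noise_s, bap_shifts=shifts
        )
        maxima[r] = scores.max()
    return maxima


def matched_run_scores(
    n_runs: int,
    window: float,
    design: StudyDesign = StudyDesign(),
    seed: int = 0,
    jitter_sd: float = 0.0,
) -> np.ndarray:
    """Detector score of the matched spine group, one per independent run.

    Only the matched group is simulated (the null groups of the same run do
    not influence its score), which makes large batches cheap.  The query
    trains and membrane-noise streams depend on ``seed`` but *not* on
    ``jitter_sd``, so runs with different jitter levels are paired (common
    random numbers): each condition's mean is unbiased and the comparison
    across jitter levels is far more stable.
    """
    geom = design.geom()
    lat0 = geom.latency_s(0)
    pres, posts = [], []
    for r in range(n_runs):
        base = np.random.SeedSequence([seed, _TAG_MATCHED, r])
        post = sample_poisson_refractory(
            design.rate, design.refractory, window, np.random.default_rng(base)
        )
        arrivals = post.times + lat0
        arrivals = arrivals[arrivals < window]
        pre = arrivals - design.lead
        pre = pre[pre >= 0]
        if jitter_sd > 0:
            jrng = np.random.default_rng(
                np.random.SeedSequence([seed, _TAG_JITTER, r])
            )
            pre = np.clip(pre + jrng.normal(0, jitter_sd, pre.size), 0, window - 1e-9)
            pre = np.sort(pre)
        pres.append(pre)
        posts.append(post.times + lat0)
    noise_ss = np.random.SeedSequence([seed, _TAG_NOISE])
    return simulate_scores(pres, posts, window, design.params, seed=noise_ss)


def calibrate(
    window: float,
    n_runs: int = 500,
    design: StudyDesign = StudyDesign(),
    seed: int = 0,
    target: float = 0.9,
) -> ThresholdCalibration:
    """Calibrate the potentiation threshold on a fresh null batch."""
    maxima = null_run_maxima(n_runs, window, design, seed=seed)
    return calibrate_threshold(maxima, target=target, window=window)


def detection_study(
    windows: Sequence[float] = (0.5, 1.0, 2.0),
    jitters_ms: Sequence[float] = (0.0, 1.0, 2.0),
    n_calib: int = 500,
    n_matched: int = 1000,
    n_null_eval: int = 0,
    design: StudyDesign = StudyDesign(),
    seed: int = 0,
) -> dict:
    """The detection analysis: thresholds, TPR per window, jitter TPRs.

    Calibration (seed stream ``seed*2+1``) and evaluation (stream
    ``seed*2+2``) use disjoint seed ranges.  The jitter study runs at the
    1 s window (or the middle window provided) against that window's
    threshold.  ``n_null_eval`` > 0 additionally measures the family-wise
    rejection rate on an independent null batch per window.
    """
    cal_seed, eval_seed = 2 * seed + 1, 2 * seed + 2
    out: dict = {"windows": {}, "jitter": {}}
    jitter_window = 1.0 if 1.0 in windows else windows[len(windows) // 2]
    for iw, w in enumerate(windows):
        cal = calibrate(w, n_calib, design, seed=cal_seed * 1000 + iw)
        matched = matched_run_scores(n_matched, w, design, seed=eval_seed * 1000 + iw)
        null_max = (
            null_run_maxima(n_null_eval, w, design, seed=eval_seed * 1000 + 500 + iw)
            if n_null_eval
            else np.array([])
        )
        rep = evaluate_detection(
            matched,
            null_max if n_null_eval else np.array([np.inf]),
            cal,
            window=w,
        )
        out["windows"][w] = {
            "calibration": cal,
            "tpr": rep.tpr,
            "familywise_reject": 1.0 - rep.familywise_fpr if n_null_eval else None,
            "report": rep if n_null_eval else None,
            "matched_scores": matched,
            "null_maxima": null_max,
        }
        if w == jitter_window:
            jw_cal, jw_iw = cal, iw
    for j in jitters_ms:
        matched = matched_run_scores(
            n_matched, jitter_window, design,
            seed=eval_seed * 1000 + jw_iw, jitter_sd=j * 1e-3,
        )
        out["jitter"][j] = {
            "tpr": float(np.mean(matched > jw_cal.threshold)),
            "matched_scores": matched,
        }
    out["jitter_window"] = jitter_window
    return out


def control_study(
    n_runs: int = 100,
    match_window: float = 1.0,
    control_window: float = 1.0,
    gap: float = 0.5,
    threshold: float | ThresholdCalibration | None = None,
    design: StudyDesign = StudyDesign(),
    control_params: ControlParams | None = None,
    seed: int = 0,
    continue_potentiation: bool = False,
    n_calib: int = 200,
) -> list[ControlReport]:
    """Full match-to-control pipeline over repeated simulations.

    Each run: score all axons in the match phase, set each spine group's
    potentiation state through the lagged sigmoid of its normalized score,
    then play fresh value trains through the reduced relay rule and
    classify somatic output against the matched axon's values.
    """
    from .match_phase import score_ensemble  # local import to avoid cycle

    geom = design.geom()
    if threshold is None:
        threshold = calibrate(match_window, n_calib, design, seed=seed + 7919)
    thr = threshold.threshold if isinstance(threshold, ThresholdCalibration) else threshold
    if control_params is None:
        control_params = ControlParams(noise_sd=design.params.noise_sd)
    reports = []
    for r in range(n_runs):
        ss = np.random.SeedSequence([seed, _TAG_CONTROL, r])
        q_s, ens_s, noise_s, val_s, ctrl_s = ss.spawn(5)
        query = sample_poisson_refractory(
            design.rate, design.refractory, match_window, np.random.default_rng(q_s)
        )
        arrivals0 = SpikeTrain(
            np.minimum(query.times + geom.latency_s(0), match_window - 1e-9),
            match_window,
        )
        kids = ens_s.spawn(design.n_axons)
        trains = [make_matched_train(arrivals0, design.lead)]
        trains += [
            sample_poisson_refractory(
                design.rate, design.refractory, match_window,
                np.random.default_rng(kids[i]),
            )
            for i in range(1, design.n_axons)
        ]
        ensemble = TrainEnsemble(trains, 0, match_window)
        scores = score_ensemble(ensemble, query, geom, design.params, seed=noise_s)
        elapsed = gap + match_window / 2  # time since a typical mid-window crossing
        states = [
            state_from_score(s.raw / thr, lag_tau=0.5, elapsed=elapsed) for s in scores
        ]
        vkids = val_s.spawn(design.n_axons)
        values = [
            sample_poisson_refractory(
                design.rate, design.refractory, control_window,
                np.random.default_rng(vkids[i]),
            )
            for i in range(design.n_axons)
        ]
        rep = simulate_control(
            TrainEnsemble(values, 0, control_window),
            states,
            control_params,
            seed=np.random.default_rng(ctrl_s),
            continue_potentiation=continue_potentiation,
            query_rate=query.rate,
        )
        reports.append(rep)
    return reports
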