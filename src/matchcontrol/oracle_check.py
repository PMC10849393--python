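"""Equivalence check: spine-level selection vs. the exact attention oracle.

On noiseless runs the biophysical match phase should implement the same
hard-attention lookup as :mod:`matchcontrol.attention_oracle`: the set of
spine groups whose detector score clears the calibrated threshold should
equal the set of keys the kernel-based oracle selects with the same
threshold.  This module runs that comparison end to end: fit the kernel on
noiseless data, calibrate the threshold on noiseless null runs, then count
the fraction of fresh instances on which the two selected sets coincide.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .spike_trains import SpikeTrain, TrainEnsemble, sample_poisson_refractory, \
    make_matched_train
from .dendrite import SpineParams, build_geometry
from .detection import calibrate_threshold
from .match_phase import fit_kernel, generate_fit_dataset, score_ensemble, Kernel
from .attention_oracle import AttentionInstance, attend
from .experiments import StudyDesign, null_run_maxima

__all__ = ["selection_agreement"]


def selection_agreement(
    n_instances: int = 20,
    n_axons: int = 30,
    window: float = 1.0,
    seed: int = 0,
    params: SpineParams | None = None,
    fit_sims: int = 20,
    calib_runs: int = 60,
    rate: float = 6.0,
    refractory: float = 0.05,
    lead: float = 0.007,
    kernel: Kernel | None = None,
    threshold: float | None = None,
) -> tuple[float, dict]:
    """Fraction of noiseless instances with identical selected-key sets.

    Returns ``(agreement_fraction, detail)`` where ``detail`` records the
    calibrated threshold, fit quality and per-instance set sizes.  A
    pre-fitted ``kernel``/``threshold`` may be supplied to skip those
    stages.
    """
    params = replace(params or SpineParams(), noise_sd=0.0)
    geom = build_geometry(n_axons, 10, n_branches=1, spines_per_branch=n_axons * 10)
    design = StudyDesign(rate=rate, refractory=refractory, n_axons=n_axons,
                         lead=lead, params=params, geometry=geom)

    detail: dict = {}
    if kernel is None:
        ds = generate_fit_dataset(
            n_sims=fit_sims, n_axons=n_axons, window=window, rate=rate,
            refractory=refractory, params=params, geometry=geom,
            seed=seed * 13 + 1, lead=lead,
        )
        kernel, rep = fit_kernel(ds, seed=seed * 13 + 2)
        detail["fit_test_r2"] = rep.test_r2
    if threshold is None:
        maxima = null_run_maxima(calib_runs, window, design, seed=seed * 13 + 3)
        threshold = calibrate_threshold(maxima, 0.9, window, strict=False).threshold
    detail["threshold"] = float(threshold)

    n_agree = 0
    sizes = []
    for k in range(n_instances):
        ss = np.random.SeedSequence([seed, 41, k])
        q_s, ens_s = ss.spawn(2)
        query = sample_poisson_refractory(
            rate, refractory, window, np.random.default_rng(q_s)
        )
        arrivals0 = SpikeTrain(
            query.times[query.times + geom.latency_s(0) < window] + geom.latency_s(0),
            window,
        )
        trains = [make_matched_train(arrivals0, lead)]
        trains += [
            sample_poisson_refractory(rate, refractory, window,
                                      np.random.default_rng(s)).times
            for s in ens_s.spawn(n_axons - 1)
        ]
        trains = [t if isinstance(t, SpikeTrain) else SpikeTrain(t, window)
                  for t in trains]
        ensemble = TrainEnsemble(trains, 0, window)
        scores = score_ensemble(ensemble, query, geom, params, seed=0)
        sim_sel = {i for i, s in enumerate(scores) if s.raw > threshold}

        # the oracle compares keys against the spine-local arrival times
        arrivals = [
            SpikeTrain(
                query.times[query.times + geom.latency_s(i) < window]
                + geom.latency_s(i),
                window,
            )
            for i in range(n_axons)
        ]
        oracle_sel = {
            i for i, (key, arr) in enumerate(zip(trains, arrivals))
            if attend(AttentionInstance(arr, [key], [key], kernel, threshold))[0]
        }
        sizes.append((len(sim_sel), len(oracle_sel)))
        n_agree += sim_sel == oracle_sel
    detail["set_sizes"] = sizes
    return n_agree / n_instances, detail
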