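"""Reduced dendritic-spine biophysics: voltage, NMDA gating, calcium.

This module replaces a full multi-compartment cable model with closed-form
per-spine dynamics that preserve the coincidence computation:

* Per-spine voltage = resting potential + a back-propagating action
  potential (BAP) waveform at each spine-local arrival time + an EPSP
  waveform per presynaptic spike (scaled by the number of co-located
  synapses the axon makes) + Ornstein--Uhlenbeck membrane noise.
  BAP and EPSP waveforms are differences of exponentials.
* NMDA receptors: a glutamate-bound fraction with rise/decay kinetics per
  presynaptic spike (saturating at 1), multiplied by the standard
  extracellular-Mg block sigmoid of the local voltage.
* Spine calcium: influx proportional to (bound fraction x Mg gate),
  first-order decay.
* The similarity detector is the time integral of the fourth power of the
  calcium concentration, mimicking a four-site calcium sensor such as
  calmodulin: small noise-driven calcium leaks are strongly suppressed
  while coincidence-driven transients are sharpened.

All per-step updates are linear filters or pointwise maps, so many spines
are simulated at once as ``(n_traces, n_steps)`` arrays; exponential decays
use exact exponential-Euler factors.  Each trace draws its membrane noise
from its own child seed stream, so results do not depend on how traces are
batched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .spike_trains import SpikeTrain

__all__ = [
    "SpineParams",
    "Geometry",
    "CalciumTrace",
    "DetectorScore",
    "build_geometry",
    "bap_arrivals",
    "simulate_spine",
    "simulate_scores",
    "detector_integral",
]

# [Mg]o (mM) at which the block e-fold voltage shift is referenced; the
# standard empirical constant of the Jahr-Stevens block model.
_MG_K0 = 3.57


@dataclass(frozen=True)
class SpineParams:
    """Parameters of the reduced spine model.

    Amplitudes are in mV, times in ms, calcium in arbitrary units (only
    ratios and threshold-normalized detector scores are meaningful).
    """

    bap_amplitude: float = 60.0       # BAP peak depolarization at the spine, mV
    bap_rise: float = 0.2             # ms
    bap_decay: float = 2.0            # ms
    epsp_amplitude: float = 0.9       # per-synapse EPSP peak, mV
    epsp_rise: float = 0.5            # ms
    epsp_decay: float = 5.0           # ms
    synapses_per_axon: int = 10       # co-located synapses driven by one axon
    nmda_rise: float = 6.2            # coincidence-gate rise, ms
    nmda_decay: float = 12.0          # coincidence-gate decay, ms
    mg_conc: float = 1.0              # extracellular [Mg2+], mM
    mg_slope: float = 0.062           # Mg block voltage sensitivity, 1/mV
    ca_decay: float = 6.0             # spine calcium clearance, ms
    ca_influx_rate: float = 1.0       # au/ms at fully open NMDA
    noise_sd: float = 4.0             # membrane noise SD, mV
    noise_corr_time: float = 5.0      # membrane noise correlation time, ms
    resting_potential: float = -70.0  # mV
    dt: float = 0.1                   # integration time step, ms

    def __post_init__(self) -> None:
        for name in ("bap_rise", "bap_decay", "epsp_rise", "epsp_decay",
                     "nmda_rise", "nmda_decay", "ca_decay", "noise_corr_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dt > 0.5:
            raise ValueError(
                f"dt = {self.dt} ms is too coarse for the waveform kernels (max 0.5 ms)"
            )


@dataclass(frozen=True)
class Geometry:
    """Dendritic layout: axons, co-located synapse groups and BAP latencies.

    Each of ``n_axons`` axons makes ``synapses_per_axon`` synapses on
    neighbouring spines of one branch; the group is scored as a unit.  The
    BAP arrival latency of a group grows linearly with its position along
    the branch, with ties between symmetric branches broken by branch index.
    """

    n_axons: int = 150
    synapses_per_axon: int = 10
    n_branches: int = 6
    spines_per_branch: int = 250
    latencies: np.ndarray = field(default_factory=lambda: np.empty(0))
    branch_of_group: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_spines(self) -> int:
        return self.n_axons * self.synapses_per_axon

    @property
    def n_groups(self) -> int:
        return self.n_axons

    def latency_s(self, group: int) -> float:
        """BAP arrival latency of a spine group, in seconds."""
        return float(self.latencies[group]) * 1e-3


def build_geometry(
    n_axons: int = 150,
    synapses_per_axon: int = 10,
    seed: int = 0,
    n_branches: int = 6,
    spines_per_branch: int | None = None,
    latency_min: float = 0.5,
    latency_max: float = 4.0,
) -> Geometry:
    """Lay spine groups contiguously on branches and assign BAP latencies.

    Latencies (ms) increase linearly from ``latency_min`` at the proximal
    end of each branch to ``latency_max`` at the distal tip, matching the
    few-millisecond spread of BAP arrival across a tuft.  The layout is
    deterministic; ``seed`` is accepted for interface uniformity.
    """
    del seed
    n_spines = n_axons * synapses_per_axon
    if spines_per_branch is None:
        if n_spines % n_branches:
            raise ValueError(
                f"{n_spines} spines do not divide evenly over {n_branches} branches"
            )
        spines_per_branch = n_spines // n_branches
    if n_axons * synapses_per_axon != n_branches * spines_per_branch:
        raise ValueError(
            f"inconsistent counts: {n_axons} x {synapses_per_axon} != "
            f"{n_branches} x {spines_per_branch}"
        )
    if spines_per_branch % synapses_per_axon:
        raise ValueError("axon synapse groups must be contiguous within one branch")
    groups_per_branch = spines_per_branch // synapses_per_axon
    pos = np.arange(n_axons) % groups_per_branch            # position along branch
    branch = np.arange(n_axons) // groups_per_branch
    frac = (pos + 1) / groups_per_branch
    lat = latency_min + (latency_max - latency_min) * frac
    lat = lat + 1e-4 * branch                               # symmetric-branch tie break
    return Geometry(
        n_axons, synapses_per_axon, n_branches, spines_per_branch, lat, branch
    )


def bap_arrivals(soma_spikes: SpikeTrain, geometry: Geometry, group: int) -> SpikeTrain:
    """Somatic spike times shifted by a spine group's BAP propagation latency.

    The spike count is preserved; the window is kept, so arrivals may record
    times used for matched-train construction even near the window edge.
    """
    lat = geometry.latency_s(group)
    t = soma_spikes.times + lat
    dur = max(soma_spikes.duration, float(t[-1]) + 1e-9 if t.size else 0.0)
    return SpikeTrain(t, dur, label=f"BAP arrivals g{group}")


@dataclass(frozen=True)
class CalciumTrace:
    """A sampled spine calcium concentration trace (arbitrary units)."""

    dt: float                 # ms
    values: np.ndarray        # one concentration sample per step, >= 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if np.any(v < 0):
            raise ValueError("calcium concentrations must be non-negative")

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt


@dataclass(frozen=True)
class DetectorScore:
    """Integral of the fourth power of spine calcium.

    ``raw`` is in (arbitrary units)^4 * s.  ``normalized`` is ``raw``
    divided by the calibrated potentiation threshold, so 1 marks the
    threshold; it is ``None`` until a calibration is available.
    """

    raw: float
    normalized: float | None = None

    def normalize(self, threshold: float) -> "DetectorScore":
        if threshold <= 0:
            raise ValueError("threshold must be > 0")
        return DetectorScore(self.raw, self.raw / threshold)


def detector_integral(ca: CalciumTrace) -> float:
    """Raw detector score: sum of calcium^4 times the step, in au^4 * s."""
    v = np.asarray(ca.values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("calcium trace must be finite")
    return float(np.sum(v**4) * ca.dt * 1e-3)


# ---------------------------------------------------------------------------
# vectorized engine


def _decay(tau_ms: float, dt_ms: float) -> float:
    return float(np.exp(-dt_ms / tau_ms))


def _diffexp_norm(rise: float, decay: float) -> float:
    """Peak height of exp(-t/decay) - exp(-t/rise) for unit impulses."""
    tp = rise * decay / (decay - rise) * np.log(decay / rise)
    return float(np.exp(-tp / decay) - np.exp(-tp / rise))


def _impulse_matrix(
    spike_times: Sequence[np.ndarray], n_steps: int, dt_ms: float
) -> np.ndarray:
    """Bin spike times (seconds) into per-step impulse counts, float32."""
    out = np.zeros((len(spike_times), n_steps), dtype=np.float32)
    for i, t in enumerate(spike_times):
        if len(t) == 0:
            continue
        idx = np.floor(np.asarray(t) * 1e3 / dt_ms).astype(np.int64)
        idx = idx[(idx >= 0) & (idx < n_steps)]
        np.add.at(out[i], idx, 1.0)
    return out


def _exp_filter(x: np.ndarray, tau_ms: float, dt_ms: float) -> np.ndarray:
    """y[t] = exp(-dt/tau) * y[t-1] + x[t], along the last axis."""
    a = _decay(tau_ms, dt_ms)
    return lfilter(np.array([1.0], dtype=np.float32),
                   np.array([1.0, -a], dtype=np.float32), x, axis=-1)


def _diffexp_wave(
    impulses: np.ndarray, rise: float, decay: float, amplitude: float, dt_ms: float
) -> np.ndarray:
    norm = _diffexp_norm(rise, decay)
    return (amplitude / norm) * (
        _exp_filter(impulses, decay, dt_ms) - _exp_filter(impulses, rise, dt_ms)
    )


def _ou_noise(
    n_steps: int, sd: float, corr_ms: float, dt_ms: float, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0:
        return np.zeros(n_steps, dtype=np.float32)
    a = _decay(corr_ms, dt_ms)
    w = rng.standard_normal(n_steps, dtype=np.float32)
    w *= sd * np.sqrt(1.0 - a * a)
    n = _exp_filter(w, corr_ms, dt_ms)
    return n.astype(np.float32, copy=False)


def _simulate_block(
    pre_imp: np.ndarray,
    bap_imp: np.ndarray,
    params: SpineParams,
    noise: np.ndarray | None,
    want_voltage: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Core forward pass on an impulse block; returns (calcium, voltage)."""
    p = params
    dt = p.dt
    bap_wave = _diffexp_wave(bap_imp, p.bap_rise, p.bap_decay, p.bap_amplitude, dt)
    return _simulate_block_with_bap(pre_imp, bap_wave, params, noise, want_voltage)


def _simulate_block_with_bap(
    pre_imp: np.ndarray,
    bap_wave: np.ndarray,
    params: SpineParams,
    noise: np.ndarray | None,
    want_voltage: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Forward pass given a precomputed BAP voltage waveform (broadcastable)."""
    p = params
    dt = p.dt
    v = _diffexp_wave(
        pre_imp, p.epsp_rise, p.epsp_decay, p.epsp_amplitude * p.synapses_per_axon, dt
    )
    v += bap_wave
    v += p.resting_potential
    if noise is not None:
        v += noise
    # glutamate-bound NMDA fraction, saturating at 1
    g = _diffexp_wave(pre_imp, p.nmda_rise, p.nmda_decay, 1.0, dt)
    np.clip(g, 0.0, 1.0, out=g)
    # Mg block sigmoid (Jahr-Stevens form)
    mg = 1.0 / (1.0 + (p.mg_conc / _MG_K0) * np.exp(-p.mg_slope * v))
    influx = g
    influx *= mg
    influx *= p.ca_influx_rate * dt
    ca = _exp_filter(influx, p.ca_decay, dt)
    return ca, (v if want_voltage else None)


def simulate_spine(
    pre: SpikeTrain,
    arrivals: SpikeTrain,
    params: SpineParams = SpineParams(),
    dt: float | None = None,
    seed: int | np.random.Generator = 0,
    duration: float | None = None,
) -> tuple[np.ndarray, CalciumTrace]:
    """Simulate one spine group; return (voltage trace mV, calcium trace).

    ``pre`` carries the axon's presynaptic spikes, ``arrivals`` the
    spine-local BAP arrival times.  The simulation window is the larger of
    the two train durations unless ``duration`` is given.
    """
    if dt is not None:
        params = replace(params, dt=dt)
    dur = duration if duration is not None else max(pre.duration, arrivals.duration)
    n_steps = int(round(dur * 1e3 / params.dt))
    pre_imp = _impulse_matrix([pre.times], n_steps, params.dt)
    bap_imp = _impulse_matrix([arrivals.times], n_steps, params.dt)
    rng = np.random.default_rng(seed)
    noise = _ou_noise(n_steps, params.noise_sd, params.noise_corr_time, params.dt, rng)
    ca, v = _simulate_block(pre_imp, bap_imp, params, noise[None, :], want_voltage=True)
    ca = np.maximum(ca[0], 0.0)
    return v[0].astype(float), CalciumTrace(params.dt, ca)


def simulate_scores(
    pre_trains: Sequence[np.ndarray | SpikeTrain],
    bap_trains: Sequence[np.ndarray | SpikeTrain],
    duration: float,
    params: SpineParams = SpineParams(),
    seed: int | np.random.SeedSequence = 0,
    bap_shifts: np.ndarray | None = None,
    max_block_elements: int = 16_000_000,
) -> np.ndarray:
    """Raw detector scores for many (pre, BAP-arrival) spike-train pairs.

    ``bap_trains`` may hold a single train to be shared by every pre train;
    in that case ``bap_shifts`` (seconds, one per pre train) optionally
    delays the shared arrival train per trace -- the per-spine-group
    propagation latency -- and the BAP voltage waveform is computed once and
    time-shifted, which is exact on the simulation grid.  Noise for trace
    ``i`` comes from the ``i``-th child of ``seed``, so the result is
    independent of the internal batching.
    """
    pre_times = [t.times if isinstance(t, SpikeTrain) else np.asarray(t)
                 for t in pre_trains]
    bap_times = [t.times if isinstance(t, SpikeTrain) else np.asarray(t)
                 for t in bap_trains]
    n = len(pre_times)
    shared_bap = len(bap_times) == 1
    if bap_shifts is not None and not shared_bap:
        raise ValueError("bap_shifts requires a single shared bap train")
    if not shared_bap and len(bap_times) != n:
        raise ValueError("bap_trains must have length 1 or match pre_trains")
    n_steps = int(round(duration * 1e3 / params.dt))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n) if params.noise_sd > 0 else [None] * n
    dt_s = params.dt * 1e-3
    block = max(1, max_block_elements // max(n_steps, 1))
    scores = np.empty(n, dtype=float)

    base_wave = None
    shift_steps = None
    if shared_bap:
        bap_imp0 = _impulse_matrix(bap_times[:1], n_steps, params.dt)
        base_wave = _diffexp_wave(
            bap_imp0, params.bap_rise, params.bap_decay, params.bap_amplitude, params.dt
        )
        if bap_shifts is not None:
            shift_steps = np.round(np.asarray(bap_shifts) * 1e3 / params.dt).astype(int)
            if shift_steps.shape != (n,):
                raise ValueError("bap_shifts must have one entry per pre train")
            if np.any(shift_steps < 0):
                raise ValueError("bap_shifts must be non-negative")

    for start in range(0, n, block):
        stop = min(start + block, n)
        pre_imp = _impulse_matrix(pre_times[start:stop], n_steps, params.dt)
        if shared_bap:
            if shift_steps is None:
                bap_wave = base_wave  # broadcast (1, T)
            else:
                bap_wave = np.zeros((stop - start, n_steps), dtype=np.float32)
                for j, k in enumerate(shift_steps[start:stop]):
                    if k < n_steps:
                        bap_wave[j, k:] = base_wave[0, : n_steps - k]
        else:
            bap_imp = _impulse_matrix(bap_times[start:stop], n_steps, params.dt)
            bap_wave = _diffexp_wave(
                bap_imp, params.bap_rise, params.bap_decay, params.bap_amplitude,
                params.dt,
            )
        if params.noise_sd > 0:
            noise = np.empty((stop - start, n_steps), dtype=np.float32)
            for j, child in enumerate(children[start:stop]):
                noise[j] = _ou_noise(
                    n_steps, params.noise_sd, params.noise_corr_time, params.dt,
                    np.random.default_rng(child),
                )
        else:
            noise = None
        ca, _ = _simulate_block_with_bap(pre_imp, bap_wave, params, noise)
        np.maximum(ca, 0.0, out=ca)
        ca = ca.astype(np.float64, copy=False)
        scores[start:stop] = np.sum(ca**4, axis=-1) * dt_s
    return scores
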