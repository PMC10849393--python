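"""Control phase: short-term potentiation and value transmission to the soma.

After the match phase, each spine group's normalized detector score is
mapped through a steep sigmoid to a target potentiation factor (1 = no
potentiation, 8 = full potentiation of the fast synaptic conductance); the
realized factor lags the target with a first-order time constant of 500 ms,
modelling the finite speed of any plausible potentiation machinery.

Transmission is reduced to an all-or-none relay: an axon whose factor is at
or above the dendritic-spike initiation level drives a somatic spike for
each of its value spikes (fixed latency, high per-spike success
probability, somatic refractoriness); sub-threshold axons do not transmit.
Background noise adds a low rate of spurious somatic spikes.  Somatic
output is scored against the matched axon's value train: a value spike is
*successful* if a somatic spike follows within 20 ms, and a somatic spike
is *spurious* if no matched value spike preceded it within 20 ms.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .spike_trains import SpikeTrain, TrainEnsemble

__all__ = [
    "PotentiationState",
    "ControlParams",
    "ControlReport",
    "potentiation_sigmoid",
    "apply_lag",
    "state_from_score",
    "simulate_control",
    "classify_spikes",
]

FACTOR_FLOOR = 1.0
FACTOR_CEIL = 8.0
SIGMOID_CENTER = 0.92   # normalized-score units (1 = potentiation threshold)
SIGMOID_WIDTH = 0.03


def potentiation_sigmoid(
    normalized_score: float | np.ndarray,
    center: float = SIGMOID_CENTER,
    width: float = SIGMOID_WIDTH,
) -> float | np.ndarray:
    """Target potentiation factor as a sigmoid of the normalized score.

    ~1 for scores well below threshold, ~8 at and above it, midpoint 4.5 at
    ``center``.  The center sits just below 1 so that a score exactly at the
    calibrated threshold already yields near-full potentiation.
    """
    s = np.asarray(normalized_score, dtype=float)
    out = FACTOR_FLOOR + (FACTOR_CEIL - FACTOR_FLOOR) / (
        1.0 + np.exp(-(s - center) / width)
    )
    return out if s.ndim else float(out)


def apply_lag(target: np.ndarray, lag_tau: float, dt: float) -> np.ndarray:
    """First-order low-pass of a target-factor trajectory, starting from 1.

    ``target`` is sampled every ``dt`` seconds; the output relaxes toward it
    with time constant ``lag_tau`` using the exact exponential-Euler update,
    so a constant target ``T`` gives ``1 + (T - 1)(1 - exp(-t/tau))``.
    """
    if lag_tau < 0:
        raise ValueError("lag_tau must be >= 0")
    x = np.asarray(target, dtype=float)
    if lag_tau == 0:
        return x.copy()
    a = 1.0 - np.exp(-dt / lag_tau)
    out = np.empty_like(x)
    y = FACTOR_FLOOR
    for i, xi in enumerate(x):
        y = y + (xi - y) * a
        out[i] = y
    return out


@dataclass
class PotentiationState:
    """Potentiation of one spine group: realized and target factor.

    The factor relaxes toward ``target_factor`` exponentially with
    ``lag_tau``; ``advance`` moves the state forward in time, keeping the
    factor inside [1, 8].
    """

    factor: float = FACTOR_FLOOR
    target_factor: float = FACTOR_FLOOR
    lag_tau: float = 0.5
    normalized_score: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        self.factor = float(np.clip(self.factor, FACTOR_FLOOR, FACTOR_CEIL))
        self.target_factor = float(np.clip(self.target_factor, FACTOR_FLOOR, FACTOR_CEIL))

    def advance(self, t: float) -> float:
        """Relax the factor up to time ``t`` (seconds) and return it."""
        if t < self.time:
            raise ValueError("cannot advance backwards in time")
        if self.lag_tau == 0:
            self.factor = self.target_factor
        else:
            w = np.exp(-(t - self.time) / self.lag_tau)
            self.factor = float(self.target_factor + (self.factor - self.target_factor) * w)
        self.time = t
        return self.factor

    def add_score(self, increment: float) -> None:
        """Accumulate normalized score and retarget the sigmoid (advance first)."""
        self.normalized_score += increment
        self.target_factor = float(potentiation_sigmoid(self.normalized_score))


def state_from_score(
    normalized_score: float, lag_tau: float = 0.5, elapsed: float = 1.0
) -> PotentiationState:
    """Potentiation state at the start of the control phase.

    ``elapsed`` is the time since the score crossed the sigmoid (roughly
    half the match window plus the 500 ms gap); the factor has relaxed
    toward the sigmoid target for that long.
    """
    target = float(potentiation_sigmoid(normalized_score))
    if lag_tau > 0:
        factor = FACTOR_FLOOR + (target - FACTOR_FLOOR) * (1.0 - np.exp(-elapsed / lag_tau))
    else:
        factor = target
    return PotentiationState(factor, target, lag_tau, normalized_score, time=0.0)


@dataclass(frozen=True)
class ControlParams:
    """Reduced transmission rule of the control phase."""

    relay_factor: float = 6.0          # dendritic-spike initiation factor
    transmission_latency: float = 0.003  # s, value spike -> somatic spike
    transmission_p: float = 0.95       # per-spike relay success probability
    soma_refractory: float = 0.005     # s
    spurious_rate_per_mV: float = 0.05   # Hz of noise-driven somatic spikes per mV of membrane noise SD
    noise_sd: float = 4.0              # mV, ties the spurious rate to the spine model
    success_window: float = 0.020      # s, for successful/spurious classification
    score_increment: float = 0.25      # normalized score per value-spike/BAP coincidence

    @property
    def spurious_rate(self) -> float:
        return self.spurious_rate_per_mV * self.noise_sd


@dataclass(frozen=True)
class ControlReport:
    """Somatic output of a control phase with per-spike bookkeeping."""

    soma_spikes: SpikeTrain
    pct_successful: float
    pct_spurious: float
    query_rate: float              # Hz of the match-phase query train
    n_matched_value_spikes: int
    n_soma_spikes: int
    zero_denominator: bool = False  # True when a 0/0 fraction was reported as 0
    final_factors: tuple[float, ...] = ()

    def as_dict(self) -> dict:
        return {
            "soma_spike_times": [round(float(t), 6) for t in self.soma_spikes.times],
            "pct_successful": self.pct_successful,
            "pct_spurious": self.pct_spurious,
            "query_rate": self.query_rate,
            "n_matched_value_spikes": self.n_matched_value_spikes,
            "n_soma_spikes": self.n_soma_spikes,
            "zero_denominator": self.zero_denominator,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=1))


def classify_spikes(
    soma: SpikeTrain,
    matched_value: SpikeTrain,
    window: float = 0.020,
) -> tuple[float, float]:
    """Fraction of successful matched value spikes and spurious somatic spikes.

    A matched value spike is *successful* if a somatic spike follows it
    within ``window`` seconds; somatic spikes are claimed greedily
    one-to-one in time order, so one somatic spike cannot make two value
    spikes successful.  A somatic spike is *spurious* if no matched value
    spike preceded it within the same window (independently of claiming).
    0/0 fractions are reported as 0.
    """
    mv = matched_value.times
    st = soma.times
    claimed = np.zeros(st.size, dtype=bool)
    n_success = 0
    j = 0
    for t in mv:
        while j < st.size and (st[j] <= t or claimed[j]):
            j += 1
        k = j
        while k < st.size and st[k] <= t + window:
            if not claimed[k]:
                claimed[k] = True
                n_success += 1
                break
            k += 1
    n_spurious = 0
    for t in st:
        if not np.any((mv < t) & (mv >= t - window)):
            n_spurious += 1
    pct_successful = n_success / mv.size if mv.size else 0.0
    pct_spurious = n_spurious / st.size if st.size else 0.0
    return pct_successful, pct_spurious


def simulate_control(
    value_trains: TrainEnsemble | Sequence[SpikeTrain],
    states: Sequence[PotentiationState],
    params: ControlParams = ControlParams(),
    seed: int | np.random.Generator = 0,
    continue_potentiation: bool = False,
    matched_index: int | None = None,
    query_rate: float = 6.0,
) -> ControlReport:
    """Simulate the control phase with the reduced relay rule.

    Each value spike of an axon whose potentiation factor (at that moment)
    is at least ``params.relay_factor`` elicits a somatic spike after the
    transmission latency with probability ``transmission_p``, subject to
    somatic refractoriness.  Membrane noise adds homogeneous-Poisson
    spurious spikes.  With ``continue_potentiation``, every somatic spike
    that follows an axon's value spike within the success window increments
    that axon's score (the control-phase analogue of NMDA coincidence), so
    weakly potentiated axons keep potentiating; factors always keep
    relaxing toward their targets either way.
    """
    if isinstance(value_trains, TrainEnsemble):
        trains = value_trains.trains
        if matched_index is None:
            mi = value_trains.matched_indices
            matched_index = mi[0] if mi else None
    else:
        trains = list(value_trains)
    if len(states) != len(trains):
        raise ValueError("need one potentiation state per axon")
    duration = trains[0].duration
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # event queue: (time, priority, kind, axon)
    heap: list[tuple[float, int, str, int]] = []
    for a, tr in enumerate(trains):
        for t in tr.times:
            heapq.heappush(heap, (float(t), 1, "value", a))
    if params.spurious_rate > 0:
        n_noise = rng.poisson(params.spurious_rate * duration)
        for t in np.sort(rng.uniform(0, duration, n_noise)):
            heapq.heappush(heap, (float(t), 0, "soma", -1))

    soma_times: list[float] = []
    last_soma = -np.inf
    recent_values: dict[int, list[float]] = {a: [] for a in range(len(trains))}

    while heap:
        t, _, kind, a = heapq.heappop(heap)
        if kind == "value":
            recent_values[a].append(t)
            if states[a].advance(t) >= params.relay_factor:
                if rng.random() < params.transmission_p:
                    heapq.heappush(heap, (t + params.transmission_latency, 0, "soma", a))
        else:  # somatic spike (relayed or noise-driven)
            if t >= duration:
                continue
            if t - last_soma < params.soma_refractory:
                continue
            last_soma = t
            soma_times.append(t)
            if continue_potentiation:
                for b, vs in recent_values.items():
                    if any(t - params.success_window <= v < t for v in vs):
                        states[b].advance(t)
                        states[b].add_score(params.score_increment)

    for st in states:
        st.advance(duration)

    soma = SpikeTrain(np.array(sorted(set(soma_times))), duration, label="soma (control)")
    if matched_index is not None:
        pct_s, pct_sp = classify_spikes(soma, trains[matched_index], params.success_window)
        n_mv = len(trains[matched_index])
    else:
        pct_s, pct_sp = 0.0, (1.0 if len(soma) else 0.0)
        n_mv = 0
    zero_den = (n_mv == 0) or (len(soma) == 0)
    return ControlReport(
        soma_spikes=soma,
        pct_successful=pct_s,
        pct_spurious=pct_sp,
        query_rate=query_rate,
        n_matched_value_spikes=n_mv,
        n_soma_spikes=len(soma),
        zero_denominator=zero_den,
        final_factors=tuple(s.factor for s in states),
    )
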