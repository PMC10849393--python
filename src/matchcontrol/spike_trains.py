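"""Spike-train generation, transformation and serialization.

All spike trains in the package -- queries (somatic activity), keys and
values (axonal activity) -- are carried by :class:`SpikeTrain`: a strictly
increasing array of spike times in seconds on ``[0, duration)``.

Random trains are sampled from a Poisson process with an absolute
refractory dead time. By default the exponential-interval rate is inflated
to ``rate / (1 - rate * refractory)`` so that the *realized* long-run rate
equals the nominal rate despite the dead time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "TrainEnsemble",
    "sample_poisson_refractory",
    "make_matched_train",
    "jitter",
    "concatenate_phases",
    "generate_ensemble",
    "save_ensemble",
    "load_ensemble",
]


@dataclass(frozen=True)
class SpikeTrain:
    """An ordered set of spike times on a finite window.

    Parameters
    ----------
    times
        Spike times in seconds, strictly increasing, all in ``[0, duration)``.
    duration
        Window length in seconds (> 0).
    label
        Free-text description (e.g. ``"axon 17 key"``).
    refractory
        Dead time (s) enforced at generation, recorded as metadata.
        ``0.0`` when unknown or not applicable (e.g. after jitter).
    """

    times: np.ndarray
    duration: float
    label: str = ""
    refractory: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if t.ndim != 1:
            raise ValueError("times must be a 1-D array")
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if t[0] < 0 or t[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_spikes(self) -> int:
        return len(self)

    @property
    def rate(self) -> float:
        """Realized mean rate in Hz."""
        return len(self) / self.duration

    def shift(self, offset: float, duration: float | None = None) -> "SpikeTrain":
        """Shift all spikes by ``offset`` seconds, dropping any that leave the window."""
        dur = self.duration if duration is None else duration
        t = self.times + offset
        t = t[(t >= 0) & (t < dur)]
        return SpikeTrain(t, dur, self.label, self.refractory)


@dataclass
class TrainEnsemble:
    """One spike train per axon, with at most two designated matched axons.

    ``matched_index`` is ``None``, an int, or a tuple of two ints; the
    experiments exercise 0, 1 or 2 matched axons out of 150.
    """

    trains: list[SpikeTrain]
    matched_index: int | tuple[int, int] | None = None
    window: float = 1.0

    def __post_init__(self) -> None:
        if not self.trains:
            raise ValueError("ensemble must contain at least one train")
        durs = {t.duration for t in self.trains}
        if len(durs) != 1:
            raise ValueError(f"all trains must share one duration, got {sorted(durs)}")
        idx = self.matched_index
        if idx is not None:
            idxs = (idx,) if isinstance(idx, (int, np.integer)) else tuple(idx)
            if len(idxs) > 2:
                raise ValueError("at most 2 matched axons are supported")
            for i in idxs:
                if not 0 <= i < len(self.trains):
                    raise IndexError(f"matched index {i} out of range")

    @property
    def matched_indices(self) -> tuple[int, ...]:
        idx = self.matched_index
        if idx is None:
            return ()
        if isinstance(idx, (int, np.integer)):
            return (int(idx),)
        return tuple(int(i) for i in idx)

    @property
    def n_axons(self) -> int:
        return len(self.trains)

    @property
    def duration(self) -> float:
        return self.trains[0].duration


def sample_poisson_refractory(
    rate: float,
    refractory: float,
    duration: float,
    seed: int | np.random.Generator,
    compensate_dead_time: bool = True,
    label: str = "",
) -> SpikeTrain:
    """Sample a Poisson spike train with an absolute refractory dead time.

    Inter-spike intervals are ``refractory + Exp(base_rate)``.  With
    ``compensate_dead_time`` (default) the base rate is inflated to
    ``rate / (1 - rate * refractory)`` so the realized mean rate over a long
    window equals the nominal ``rate`` (in Hz).  With the flag off, the base
    exponential rate is the nominal rate and the realized rate is lower.

    Raises
    ------
    ValueError
        If ``rate * refractory >= 1`` with compensation on: the dead time
        alone makes the nominal rate unreachable.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if refractory < 0:
        raise ValueError("refractory must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if rate == 0:
        return SpikeTrain(np.empty(0), duration, label, refractory)
    if compensate_dead_time:
        if rate * refractory >= 1:
            raise ValueError(
                f"nominal rate {rate} Hz is unreachable with a {refractory}s dead "
                f"time (rate * refractory = {rate * refractory:.3g} >= 1)"
            )
        base_rate = rate / (1.0 - rate * refractory)
    else:
        base_rate = rate
    rng = np.random.default_rng(seed)
    # Draw intervals in blocks until the window is covered.
    mean_isi = refractory + 1.0 / base_rate
    times: list[np.ndarray] = []
    t_last = 0.0
    # first spike: process starts unrefractory at t=0
    block = max(16, int(duration / mean_isi * 1.3) + 8)
    first = True
    while t_last < duration:
        isi = rng.exponential(1.0 / base_rate, size=block) + refractory
        if first:
            isi[0] -= refractory  # no dead time before the first spike
            first = False
        tt = t_last + np.cumsum(isi)
        times.append(tt)
        t_last = tt[-1]
    t = np.concatenate(times)
    t = t[t < duration]
    return SpikeTrain(t, duration, label, refractory)


def make_matched_train(
    post_arrivals: SpikeTrain, lead: float = 0.007, label: str = "matched"
) -> SpikeTrain:
    """Construct the matched presynaptic train: one spike ``lead`` seconds
    before each spine-local BAP arrival.

    Arrivals earlier than ``lead`` would map below zero and are dropped.
    """
    if lead < 0:
        raise ValueError("lead must be >= 0")
    t = post_arrivals.times - lead
    t = t[t >= 0]
    return SpikeTrain(t, post_arrivals.duration, label)


def jitter(train: SpikeTrain, sigma: float, seed: int | np.random.Generator) -> SpikeTrain:
    """Add independent Gaussian jitter (SD ``sigma`` seconds) to every spike.

    The output is re-sorted; spikes pushed outside ``[0, duration)`` are
    clipped to the boundary (not wrapped).  Refractory violations introduced
    by jitter are allowed, so the ``refractory`` metadata is reset to 0.
    Exactly coincident times after clipping are separated by a nanosecond to
    preserve strict ordering.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0 or len(train) == 0:
        return replace(train, refractory=train.refractory if sigma == 0 else 0.0)
    rng = np.random.default_rng(seed)
    t = train.times + rng.normal(0.0, sigma, size=len(train))
    eps = 1e-9
    t = np.clip(t, 0.0, train.duration - eps)
    t = np.sort(t)
    # break exact ties introduced by clipping
    for i in range(1, t.size):
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + eps
    t = t[t < train.duration]
    return SpikeTrain(t, train.duration, train.label, refractory=0.0)


def concatenate_phases(key: SpikeTrain, value: SpikeTrain, gap: float = 0.5) -> SpikeTrain:
    """Temporally concatenate a key train and a value train with a silent gap.

    The output window is ``key.duration + gap + value.duration``; value
    spikes are offset by ``key.duration + gap``.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    offset = key.duration + gap
    t = np.concatenate([key.times, value.times + offset])
    return SpikeTrain(
        t,
        key.duration + gap + value.duration,
        label=(key.label or value.label),
        refractory=0.0,
    )


def generate_ensemble(
    n_axons: int,
    rate: float,
    refractory: float,
    window: float,
    matched: int,
    seed: int,
    query: SpikeTrain | None = None,
    matched_arrivals: SpikeTrain | Sequence[SpikeTrain] | None = None,
    lead: float = 0.007,
    jitter_sd: float = 0.0,
    compensate_dead_time: bool = True,
) -> TrainEnsemble:
    """Generate a key ensemble: ``matched`` matched axons, the rest Poisson.

    Per-axon seeds are spawned deterministically from the master ``seed``.
    Matched trains are built from ``matched_arrivals`` (the spine-local BAP
    arrival times of the matched groups); if omitted, ``query`` is used
    directly (zero-latency arrivals). Matched axons occupy indices ``0`` and,
    when ``matched == 2``, ``1``.
    """
    if matched not in (0, 1, 2):
        raise ValueError("matched must be 0, 1 or 2")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_axons + matched)
    trains: list[SpikeTrain] = []
    if matched:
        if matched_arrivals is None:
            if query is None:
                raise ValueError("matched > 0 requires query or matched_arrivals")
            arrivals = [query] * matched
        elif isinstance(matched_arrivals, SpikeTrain):
            arrivals = [matched_arrivals] * matched
        else:
            arrivals = list(matched_arrivals)
            if len(arrivals) != matched:
                raise ValueError("need one arrival train per matched axon")
    for i in range(n_axons):
        rng = np.random.default_rng(children[i])
        if i < matched:
            tr = make_matched_train(arrivals[i], lead, label=f"axon {i} (matched)")
            if jitter_sd > 0:
                tr = jitter(tr, jitter_sd, np.random.default_rng(children[n_axons + i]))
        else:
            tr = sample_poisson_refractory(
                rate, refractory, window, rng,
                compensate_dead_time=compensate_dead_time, label=f"axon {i}",
            )
        trains.append(tr)
    matched_index: int | tuple[int, int] | None
    matched_index = None if matched == 0 else (0 if matched == 1 else (0, 1))
    return TrainEnsemble(trains, matched_index, window)


# ---------------------------------------------------------------------------
# serialization: CSV of (train_id, spike_time_s) + JSON sidecar


def save_ensemble(ensemble: TrainEnsemble, csv_path: str | Path) -> None:
    """Write an ensemble as a spike-time CSV plus a ``.json`` sidecar.

    The CSV has columns ``train_id, spike_time_s``; the sidecar records
    durations, labels, refractory metadata and the matched index. Times are
    stored with microsecond precision.
    """
    csv_path = Path(csv_path)
    rows = [
        (i, round(float(t), 6))
        for i, tr in enumerate(ensemble.trains)
        for t in tr.times
    ]
    df = pd.DataFrame(rows, columns=["train_id", "spike_time_s"])
    df.to_csv(csv_path, index=False, float_format="%.6f")
    meta = {
        "window": ensemble.window,
        "matched_index": list(ensemble.matched_indices) or None,
        "trains": [
            {
                "train_id": i,
                "duration": tr.duration,
                "label": tr.label,
                "refractory": tr.refractory,
            }
            for i, tr in enumerate(ensemble.trains)
        ],
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_ensemble(csv_path: str | Path) -> TrainEnsemble:
    """Read an ensemble written by :func:`save_ensemble`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    trains = []
    for info in meta["trains"]:
        t = df.loc[df["train_id"] == info["train_id"], "spike_time_s"].to_numpy(float)
        trains.append(
            SpikeTrain(np.sort(t), info["duration"], info["label"], info["refractory"])
        )
    mi = meta["matched_index"]
    matched: int | tuple[int, int] | None
    if mi is None:
        matched = None
    elif len(mi) == 1:
        matched = mi[0]
    else:
        matched = (mi[0], mi[1])
    return TrainEnsemble(trains, matched, meta["window"])
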