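"""Exact sparse hard-attention reference, for equivalence tests.

The biophysical pipeline emulates a hard attention lookup: score every key
spike train against the query with a temporally smeared dot product, select
the keys whose score clears a high threshold, and output the union of the
selected keys' value trains.  This module computes that lookup exactly from
a kernel and a threshold, with no simulation, so the spine-level machinery
can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .spike_trains import SpikeTrain
from .match_phase import Kernel, predict_kernel_model

__all__ = ["AttentionInstance", "smoothed_overlap", "attend"]


@dataclass(frozen=True)
class AttentionInstance:
    """A single hard-attention problem: one query, aligned keys and values."""

    query: SpikeTrain
    keys: list[SpikeTrain]
    values: list[SpikeTrain]
    kernel: Kernel
    threshold: float

    def __post_init__(self) -> None:
        if len(self.keys) != len(self.values):
            raise ValueError("keys and values must be aligned one-to-one")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


def smoothed_overlap(query: SpikeTrain, key: SpikeTrain, kernel: Kernel) -> float:
    """Temporally smeared dot product of two spike trains.

    Equal by contract to :func:`matchcontrol.match_phase.predict_kernel_model`
    (shared implementation): the sum of ``K(t_query - t_key)`` over all
    spike pairs.  With a delta-like kernel this reduces to the Euclidean
    inner product of the binned spike vectors.
    """
    return predict_kernel_model(kernel, key, query)


def attend(instance: AttentionInstance) -> tuple[list[int], SpikeTrain]:
    """Hard attention lookup: threshold-selected keys, union of their values.

    Returns the indices of all keys whose smoothed overlap with the query
    exceeds the threshold, and the merged (sorted, de-duplicated) value
    train.  No key above threshold yields an empty output -- the no-match
    ("recall failure") case.
    """
    scores = [smoothed_overlap(instance.query, k, instance.kernel) for k in instance.keys]
    selected = [i for i, s in enumerate(scores) if s > instance.threshold]
    if selected:
        dur = max(instance.values[i].duration for i in selected)
        times = np.unique(np.concatenate([instance.values[i].times for i in selected]))
    else:
        dur = instance.values[0].duration if instance.values else instance.query.duration
        times = np.empty(0)
    return selected, SpikeTrain(times, dur, label="attention output")
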