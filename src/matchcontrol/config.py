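"""Experiment configuration: schema, (de)serialization, resolved hashes."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .dendrite import SpineParams
from .control_phase import ControlParams

__all__ = ["ExperimentConfig", "config_hash"]

_ALLOWED_WINDOWS = (0.5, 1.0, 2.0)
_ALLOWED_JITTERS = (0.0, 1.0, 2.0)


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved configuration of a full experiment run.

    Every stochastic quantity derives from ``seed``; reports embed the hash
    of the resolved config so outputs are traceable to their settings.
    """

    seed: int = 0
    rate: float = 6.0
    refractory: float = 0.05
    n_axons: int = 150
    lead: float = 0.007
    windows: tuple[float, ...] = (0.5, 1.0, 2.0)
    jitters_ms: tuple[float, ...] = (0.0, 1.0, 2.0)
    n_calib: int = 500
    n_matched: int = 1000
    n_null_eval: int = 0
    kernel_sims: int = 100
    offset_reps: int = 300
    offset_min_ms: float = -20.0
    offset_max_ms: float = 30.0
    control_runs: int = 100
    control_window: float = 1.0
    gap: float = 0.5
    spine: SpineParams = field(default_factory=SpineParams)
    control: ControlParams = field(default_factory=ControlParams)
    out_dir: str = "results"
    make_figures: bool = True

    def __post_init__(self) -> None:
        errors = []
        if self.seed < 0:
            errors.append("seed: must be >= 0")
        for name in ("n_axons", "n_calib", "n_matched", "kernel_sims",
                     "offset_reps", "control_runs"):
            if getattr(self, name) < 0:
                errors.append(f"{name}: must be >= 0")
        for w in self.windows:
            if w not in _ALLOWED_WINDOWS:
                errors.append(f"windows: {w} not in {_ALLOWED_WINDOWS}")
        for j in self.jitters_ms:
            if j not in _ALLOWED_JITTERS:
                errors.append(f"jitters_ms: {j} not in {_ALLOWED_JITTERS}")
        if self.rate < 0 or self.rate * self.refractory >= 1:
            errors.append("rate: must be >= 0 and reachable given the refractory")
        if errors:
            raise ValueError("invalid config fields: " + "; ".join(errors))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["windows"] = list(self.windows)
        d["jitters_ms"] = list(self.jitters_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"invalid config fields: {sorted(unknown)}")
        if "spine" in d and isinstance(d["spine"], dict):
            d["spine"] = SpineParams(**d["spine"])
        if "control" in d and isinstance(d["control"], dict):
            d["control"] = ControlParams(**d["control"])
        for key in ("windows", "jitters_ms"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def hash(self) -> str:
        return config_hash(self)


def config_hash(config: ExperimentConfig) -> str:
    """Stable short hash of the resolved scientific configuration.

    Presentation-only fields (output directory, figure toggle) are excluded,
    so runs that differ only in where they write are recognized as identical.
    """
    d = config.to_dict()
    d.pop("out_dir", None)
    d.pop("make_figures", None)
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
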