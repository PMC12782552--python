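"""Ground-truth ledgers recorded by the generators for recovery tests."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GroundTruth"]


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class GroundTruth:
    """Generator-side record of everything the analysis should recover.

    Any subset of fields may be populated depending on which generators ran.
    ``merge`` combines ledgers from separate generator calls into one record
    for a full synthetic experiment.
    """

    #: cycle boundaries, shape (n_cycles, 2): [start, end) in seconds
    cycles: np.ndarray | None = None
    #: contraction windows, shape (n_cycles, 2)
    contraction_windows: np.ndarray | None = None
    #: unit id -> sorted true spike times (s)
    spikes: dict[str, np.ndarray] = field(default_factory=dict)
    #: unit id -> phase class label
    unit_classes: dict[str, str] = field(default_factory=dict)
    #: NS resting potential (mV) and per-cycle hyperpolarization depths (mV)
    ns_resting_vm: float | None = None
    ns_depths: np.ndarray | None = None
    #: behavioral steps: list of dicts with step/phase boundary times (s)
    steps: list[dict] = field(default_factory=list)

    def validate(self) -> None:
        """Internal consistency: sorted events inside the recorded span."""
        if self.cycles is not None:
            c = np.asarray(self.cycles)
            if not np.all(np.diff(c[:, 0]) > 0):
                raise ValueError("cycle starts must be strictly increasing")
            if not np.all(c[:, 1] > c[:, 0]):
                raise ValueError("cycle ends must exceed starts")
            span = (c[0, 0], c[-1, 1])
            for uid, st in self.spikes.items():
                if st.size and not np.all(np.diff(st) > 0):
                    raise ValueError(f"unit {uid}: spike times not sorted")
                if st.size and (st[0] < span[0] - 1e-9 or st[-1] > span[1] + 1e-9):
                    raise ValueError(f"unit {uid}: spikes outside recording span")
        for s in self.steps:
            if not s["t_start"] < s["t_end"]:
                raise ValueError("step boundaries must be ordered")

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        out = GroundTruth(
            cycles=self.cycles if self.cycles is not None else other.cycles,
            contraction_windows=(
                self.contraction_windows
                if self.contraction_windows is not None
                else other.contraction_windows
            ),
            spikes={**self.spikes, **other.spikes},
            unit_classes={**self.unit_classes, **other.unit_classes},
            ns_resting_vm=(
                self.ns_resting_vm if self.ns_resting_vm is not None else other.ns_resting_vm
            ),
            ns_depths=self.ns_depths if self.ns_depths is not None else other.ns_depths,
            steps=self.steps or other.steps,
        )
        return out

    # -- serialization --------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "cycles": _jsonify(self.cycles),
            "contraction_windows": _jsonify(self.contraction_windows),
            "spikes": _jsonify(self.spikes),
            "unit_classes": self.unit_classes,
            "ns_resting_vm": self.ns_resting_vm,
            "ns_depths": _jsonify(self.ns_depths),
            "steps": _jsonify(self.steps),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            cycles=None if d["cycles"] is None else np.asarray(d["cycles"]),
            contraction_windows=(
                None
                if d["contraction_windows"] is None
                else np.asarray(d["contraction_windows"])
            ),
            spikes={k: np.asarray(v) for k, v in d["spikes"].items()},
            unit_classes=d["unit_classes"],
            ns_resting_vm=d["ns_resting_vm"],
            ns_depths=None if d["ns_depths"] is None else np.asarray(d["ns_depths"]),
            steps=d["steps"],
        )
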