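"""Run configuration: every stage parameter in one serializable record.

The default profile is frozen to the constants the analysis is built
around (burst criteria 0.5 s / 10 spikes / 8 Hz, bFF bins 0.05 and 0.5 s,
Gaussian sigmas 0.15 / 5 / 0.25 s, rhythmicity 2 peaks at r > 0.25,
4-cycle profile averaging); any deviation shows up as an explicit diff
against ``RunConfig()``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # burst / cycle criteria
    max_isi: float = 0.5  # s
    min_spikes: int = 10
    min_mff: float = 8.0  # Hz
    cycle_mode: str = "start_to_start"
    # binned firing frequency
    bff_bin_fine: float = 0.05  # s, intracellular correlation grid
    bff_bin_coarse: float = 0.5  # s, phase/rhythmicity grid
    bff_sigma: float = 0.15  # s, pre-correlation smoothing
    # intracellular
    baseline_sigma: float = 5.0  # s
    # rhythmicity and phase profiles
    rhythm_min_peaks: int = 2
    rhythm_min_r: float = 0.25
    rhythm_cycles: int = 4
    profile_cycles: int = 4
    n_phase_bins: int = 50
    onset_tol: float = 0.05
    onset_baseline_frac: float = 0.2
    # spike sorting
    threshold_k: float = 5.0
    detect_window: float = 0.003  # s
    min_cluster_size: int = 20
    max_embed: int = 1000
    embed_seed: int = 0
    # behavior
    kin_sigma: float = 0.25  # s
    likelihood_floor: float = 0.9
    gap_limit: int = 5
    min_step_separation: float = 2.0  # s
    kneedle_sensitivity: float = 1.0
    fps: float = 60.0
    # run control
    seed: int = 1
    simulate: bool = True
    pulse: tuple[float, float] | None = None

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        if d["pulse"] is not None:
            d["pulse"] = list(d["pulse"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if d.get("pulse") is not None:
            d["pulse"] = tuple(d["pulse"])
        return cls(**d)

    def diff(self) -> dict:
        """Fields differing from the frozen default profile."""
        ref = asdict(RunConfig())
        cur = asdict(self)
        return {k: cur[k] for k in cur if cur[k] != ref[k]}

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
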