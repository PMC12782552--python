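"""Convenience builders for complete synthetic fictive-crawling episodes.

These compose the oscillator, unit, extracellular and NS generators into the
standard benchmark recordings used throughout the test surface: a DP-nerve
render with DE-3 plus phase-tuned companion units, and paired NS traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..timeseries import TimeSeries
from .ground_truth import GroundTruth
from .intracellular import gen_ns_trace
from .oscillator import Cycles, gen_cycles
from .specs import KinematicSpec, NSSpec, OscillatorSpec, UnitSpec, make_template
from .units import gen_unit_spikes, render_extracellular

__all__ = [
    "EphysEpisode",
    "default_unit_specs",
    "standard_episode",
    "class_windows",
]

#: Default (onset, offset) phase windows per unit class.  DE-3 and in-phase
#: units occupy the contraction window; anti-phase units fire in between
#: DE-3 bursts; early-onset units start late in the preceding cycle and stop
#: inside the DE-3 window.
CLASS_WINDOWS = {
    "DE3": (0.0, None),  # None -> the oscillator's contraction duty
    "in_phase": (0.02, 0.30),
    "anti_phase": (0.36, 1.0),
    "in_phase_early_onset": (0.9, 0.2),
}


def class_windows(contraction_duty: float) -> dict[str, tuple[float, float]]:
    out = {}
    for cls, (a, b) in CLASS_WINDOWS.items():
        out[cls] = (a, contraction_duty if b is None else b)
    return out


def default_unit_specs(
    osc: OscillatorSpec,
    snr: float = 8.0,
    noise_sd: float = 1.0,
    rate: float = 10_000.0,
) -> dict[str, UnitSpec]:
    """The standard 3-unit DP-nerve benchmark at a given SNR.

    DE-3 is the largest unit (as in real DP recordings); the companion
    anti-phase and early-onset units differ in amplitude, width and leading
    polarity.  ``snr`` is the peak amplitude of the smallest unit over the
    noise sd.
    """
    win = class_windows(osc.contraction_duty)
    a0 = snr * noise_sd
    return {
        "DE3": UnitSpec(
            unit_class="DE3",
            peak_rate=20.0,
            baseline_rate=0.0,
            onset_phase=win["DE3"][0],
            offset_phase=win["DE3"][1],
            waveform=make_template(2.0 * a0, width_ms=1.2, rate=rate, polarity=-1),
            refractory=0.005,
        ),
        "anti": UnitSpec(
            unit_class="anti_phase",
            peak_rate=12.0,
            baseline_rate=0.2,
            onset_phase=win["anti_phase"][0],
            offset_phase=win["anti_phase"][1],
            waveform=make_template(
                1.0 * a0, width_ms=0.8, rate=rate, polarity=-1, asymmetry=0.8
            ),
            refractory=0.005,
        ),
        "early": UnitSpec(
            unit_class="in_phase_early_onset",
            peak_rate=15.0,
            baseline_rate=0.2,
            onset_phase=win["in_phase_early_onset"][0],
            offset_phase=win["in_phase_early_onset"][1],
            waveform=make_template(
                1.4 * a0, width_ms=1.5, rate=rate, polarity=1, asymmetry=0.6
            ),
            refractory=0.005,
        ),
    }


@dataclass
class EphysEpisode:
    """One synthetic nerve recording with its complete ground truth."""

    trace: TimeSeries
    cycles: Cycles
    unit_specs: dict[str, UnitSpec]
    spikes: dict[str, np.ndarray]
    ledger: pd.DataFrame  # embedded-event ledger from the renderer
    truth: GroundTruth
    noise_sd: float


def standard_episode(
    seed: int = 0,
    osc: OscillatorSpec | None = None,
    snr: float = 8.0,
    noise_sd: float = 1.0,
    rate: float = 10_000.0,
    unit_specs: dict[str, UnitSpec] | None = None,
) -> EphysEpisode:
    """Build the standard synthetic DP-nerve episode for a given seed.

    Cycle jitter, spike sampling and trace noise all derive from ``seed``
    (sub-seeds are spaced so streams are independent but reproducible).
    """
    if osc is None:
        osc = OscillatorSpec(seed=seed)
    else:
        osc = OscillatorSpec(**{**osc.__dict__, "seed": seed})
    cycles, truth = gen_cycles(osc)
    specs = unit_specs or default_unit_specs(osc, snr=snr, noise_sd=noise_sd, rate=rate)

    spikes: dict[str, np.ndarray] = {}
    for i, (uid, us) in enumerate(specs.items()):
        st, tr = gen_unit_spikes(us, cycles, seed=seed * 1000 + 17 * (i + 1), unit_id=uid)
        spikes[uid] = st
        truth = truth.merge(tr)

    duration = cycles.span[1] + 0.05
    trace, ledger = render_extracellular(
        [(spikes[uid], specs[uid].waveform) for uid in specs],
        rate=rate,
        noise_sd=noise_sd,
        duration=duration,
        seed=seed * 1000 + 999,
    )
    ledger["unit_id"] = [list(specs)[u] for u in ledger["unit"]]
    return EphysEpisode(
        trace=trace,
        cycles=cycles,
        unit_specs=specs,
        spikes=spikes,
        ledger=ledger,
        truth=truth,
        noise_sd=noise_sd,
    )
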