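"""Phase-tuned spike trains and extracellular rendering."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..timeseries import TimeSeries
from .ground_truth import GroundTruth
from .oscillator import Cycles
from .specs import UnitSpec

__all__ = ["gen_unit_spikes", "render_extracellular"]


def _in_window(phase: np.ndarray, onset: float, offset: float) -> np.ndarray:
    """Membership of phases in the wrapped window [onset, offset)."""
    if onset < offset:
        return (phase >= onset) & (phase < offset)
    # wrapped window, e.g. early-onset units: [0.9, 1) U [0, 0.2)
    return (phase >= onset) | (phase < offset)


def gen_unit_spikes(
    spec: UnitSpec, cycles: Cycles, seed: int = 0, unit_id: str | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Sample one unit's spike train over the cycles of the oscillator.

    Piecewise-constant-rate Poisson process by thinning: rate is
    ``peak_rate`` at phases inside the unit's (wrapped) tuning window and
    ``baseline_rate`` elsewhere, with a hard absolute refractory period
    applied afterwards.  Bit-reproducible for a given (spec, cycles, seed).
    """
    spec.validate()
    if spec.onset_phase == spec.offset_phase and spec.peak_rate > spec.baseline_rate:
        raise ValueError("empty tuning window: onset_phase == offset_phase")
    rng = np.random.default_rng(seed)
    t0, t1 = cycles.span
    span = t1 - t0
    rate_max = max(spec.peak_rate, spec.baseline_rate)
    uid = unit_id or spec.unit_class

    if rate_max == 0:
        times = np.empty(0)
    else:
        n_cand = rng.poisson(rate_max * span)
        cand = np.sort(t0 + span * rng.random(n_cand))
        phase = cycles.phase_of(cand)
        inside = ~np.isnan(phase)
        rate = np.full(cand.shape, spec.baseline_rate)
        hot = inside & _in_window(phase, spec.onset_phase, spec.offset_phase)
        rate[hot] = spec.peak_rate
        keep = rng.random(cand.size) * rate_max < rate
        times = cand[keep]
        if spec.refractory > 0 and times.size:
            kept = [times[0]]
            for t in times[1:]:
                if t - kept[-1] >= spec.refractory:
                    kept.append(t)
            times = np.asarray(kept)

    truth = GroundTruth(
        cycles=cycles.bounds.copy(),
        contraction_windows=cycles.contraction.copy(),
        spikes={uid: times.copy()},
        unit_classes={uid: spec.unit_class},
    )
    truth.validate()
    return times, truth


def render_extracellular(
    units: list[tuple[np.ndarray, np.ndarray]],
    rate: float = 10_000.0,
    noise_sd: float = 1.0,
    duration: float | None = None,
    seed: int = 0,
    units_label: str = "uV",
) -> tuple[TimeSeries, pd.DataFrame]:
    """Render spike trains into a noisy extracellular trace.

    Each (spike_times, template) pair is stamped into the trace with the
    template extremum aligned on the spike sample; overlapping spikes simply
    superpose.  I.i.d. Gaussian noise of ``noise_sd`` is added.  Returns the
    trace and the embedded-event ledger (unit index, time, sample).

    An empty unit list yields a pure-noise trace.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if duration is None:
        tmax = max((float(t[-1]) for t, _ in units if len(t)), default=0.0)
        duration = tmax + 0.1
    n = int(np.ceil(duration * rate))
    rng = np.random.default_rng(seed)
    trace = (
        rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    )

    rows: list[tuple[int, float, int]] = []
    for ui, (times, template) in enumerate(units):
        template = np.asarray(template, dtype=float)
        peak = int(np.argmax(np.abs(template)))
        for t in np.asarray(times, dtype=float):
            s = int(round(t * rate))
            lo = s - peak
            hi = lo + template.size
            if lo < 0 or hi > n:
                continue  # template would clip the edge; skip but log
            trace[lo:hi] += template
            rows.append((ui, t, s))
    ledger = pd.DataFrame(rows, columns=["unit", "time", "sample"])
    return TimeSeries(trace, rate=rate, units=units_label), ledger
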