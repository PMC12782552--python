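"""Synthetic nonspiking (NS) premotor membrane potential."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from ..timeseries import TimeSeries
from .ground_truth import GroundTruth
from .oscillator import Cycles
from .specs import NSSpec

__all__ = ["gen_ns_trace"]


def _hyp_bump(cycles: Cycles, rate: float, n: int, smooth_s: float) -> np.ndarray:
    """Unit-peak hyperpolarization bump train on the contraction windows.

    Raised cosine on each contraction window, Gaussian-smoothed, then
    renormalized per cycle so the smoothed bump still peaks at exactly 1
    (the programmed depth is then exact in the noiseless trace).
    """
    t = np.arange(n) / rate
    w = np.zeros(n)
    for a, b in cycles.contraction:
        i0, i1 = int(np.ceil(a * rate)), int(np.floor(b * rate))
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 <= i0 + 1:
            continue
        u = (t[i0:i1] - a) / (b - a)
        w[i0:i1] = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
    if smooth_s > 0:
        w = gaussian_filter1d(w, sigma=smooth_s * rate, mode="reflect")
    for a, b in cycles.bounds:
        i0, i1 = max(int(a * rate), 0), min(int(b * rate), n)
        peak = w[i0:i1].max() if i1 > i0 else 0.0
        if peak > 0:
            w[i0:i1] /= peak
    return w


def gen_ns_trace(
    spec: NSSpec, cycles: Cycles, rate: float = 500.0, seed: int = 0
) -> tuple[TimeSeries, GroundTruth]:
    """Generate an NS membrane-potential trace locked anti-phase to DE-3.

    Vm(t) = resting_vm - hyp(t) + drift * t + noise(t), where ``hyp`` is a
    smooth bump train supported on the contraction windows (so
    hyperpolarizations coincide with DE-3 bursts), scaled per cycle to the
    depth convention of ``spec.depth_reference``, and the noise is an
    Ornstein-Uhlenbeck process with sd ``noise_sd`` and correlation time
    ``noise_tau``.
    """
    spec.validate()
    if rate <= 0:
        raise ValueError("rate must be > 0")
    rng = np.random.default_rng(seed)
    _, t1 = cycles.span
    n = int(np.ceil(t1 * rate))
    t = np.arange(n) / rate

    w = _hyp_bump(cycles, rate, n, spec.osc_smoothness)
    if spec.depth_reference == "baseline":
        # scale each cycle's bump so the *measured* amplitude (slow-Gaussian
        # baseline at the window start minus the window minimum) equals
        # hyp_amplitude on the noiseless trace; the coupling of the scales
        # through the shared baseline converges in a few iterations
        scales = np.full(cycles.n, float(spec.hyp_amplitude))
        win = [
            (max(int(a * rate), 0), min(int(b * rate), n))
            for a, b in cycles.contraction
        ]
        for _ in range(4):
            wp = w.copy()
            for k, (a, b) in enumerate(cycles.bounds):
                i0, i1 = max(int(a * rate), 0), min(int(b * rate), n)
                wp[i0:i1] *= scales[k]
            base0 = gaussian_filter1d(-wp, spec.baseline_sigma * rate, mode="reflect")
            for k, (i0, i1) in enumerate(win):
                if i1 <= i0:
                    continue
                measured = base0[i0] - np.min(-wp[i0:i1])
                if measured > 0:
                    scales[k] *= spec.hyp_amplitude / measured
        hyp = wp
    else:
        hyp = spec.hyp_amplitude * w
    vm = spec.resting_vm - hyp + (spec.drift / 60.0) * t

    if spec.noise_sd > 0:
        # exact OU discretization: stationary sd = noise_sd
        a = np.exp(-1.0 / (rate * spec.noise_tau))
        innov = rng.standard_normal(n) * spec.noise_sd * np.sqrt(1.0 - a * a)
        innov[0] = rng.standard_normal() * spec.noise_sd
        noise = lfilter([1.0], [1.0, -a], innov)
        vm = vm + noise

    depths = np.full(cycles.n, float(spec.hyp_amplitude))
    truth = GroundTruth(
        cycles=cycles.bounds.copy(),
        contraction_windows=cycles.contraction.copy(),
        ns_resting_vm=float(spec.resting_vm),
        ns_depths=depths,
    )
    return TimeSeries(vm, rate=rate, units="mV"), truth
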