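"""Parameter specs for the synthetic crawling generators.

Defaults are the study conditions the generators emulate: a dopamine-induced
fictive-crawling episode in an isolated midbody ganglion (cycle period
~15.22 s, DE-3 contraction window ~0.32 of the cycle) and intact-animal
crawling steps (~7.49 s, elongation occupying 0.65 of the dynamic step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OscillatorSpec",
    "UnitSpec",
    "NSSpec",
    "KinematicSpec",
    "UNIT_CLASSES",
    "make_template",
]

#: Recognized motor-unit phase classes.
UNIT_CLASSES = (
    "DE3",
    "in_phase",
    "anti_phase",
    "in_phase_early_onset",
    "nonrhythmic",
)


@dataclass(frozen=True)
class OscillatorSpec:
    """Master crawling oscillator: cycle period and contraction window.

    ``contraction_duty`` is the fraction of each cycle occupied by the
    DE-3/contraction window; the remainder is the interburst (elongation)
    window.  Per-cycle periods are jittered with coefficient of variation
    ``period_cv`` (Gaussian, truncated away from zero).
    """

    period_mean: float = 15.22  # s
    period_cv: float = 0.1
    n_cycles: int = 10
    contraction_duty: float = 0.32
    seed: int = 0

    def validate(self) -> None:
        if not self.period_mean > 0:
            raise ValueError(f"period_mean must be > 0, got {self.period_mean}")
        if not 0 < self.contraction_duty < 1:
            raise ValueError(
                f"contraction_duty must be in (0, 1), got {self.contraction_duty}"
            )
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.period_cv < 0:
            raise ValueError("period_cv must be >= 0")


@dataclass(frozen=True)
class UnitSpec:
    """One motor unit: a phase-tuned point process plus a spike waveform.

    The unit fires as an inhomogeneous Poisson process at ``peak_rate``
    inside the (wrapped) phase window ``[onset_phase, offset_phase)`` of each
    cycle and at ``baseline_rate`` elsewhere, with a hard refractory period.
    ``waveform`` is the template stamped into extracellular renders.
    """

    unit_class: str = "in_phase"
    peak_rate: float = 20.0  # Hz
    baseline_rate: float = 0.0  # Hz
    onset_phase: float = 0.0
    offset_phase: float = 0.32
    waveform: np.ndarray | None = None
    refractory: float = 0.005  # s

    def validate(self) -> None:
        if self.unit_class not in UNIT_CLASSES:
            raise ValueError(f"unknown unit_class {self.unit_class!r}")
        if not self.peak_rate >= self.baseline_rate >= 0:
            raise ValueError("need peak_rate >= baseline_rate >= 0")
        if not (0 <= self.onset_phase < 1 and 0 <= self.offset_phase <= 1):
            raise ValueError("phase window bounds must lie in [0, 1]")
        if self.waveform is not None and not np.max(np.abs(self.waveform)) > 0:
            raise ValueError("waveform template must have a nonzero peak")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")


@dataclass(frozen=True)
class NSSpec:
    """Nonspiking premotor neuron membrane potential.

    The trace hyperpolarizes during each contraction window (a smooth bump
    built from a raised cosine, smoothed with kernel width
    ``osc_smoothness``) below ``resting_vm``, rides on a linear drift, and
    carries Ornstein–Uhlenbeck noise of standard deviation ``noise_sd`` and
    correlation time ``noise_tau`` (correlated, membrane-like fluctuations;
    purely white noise would vanish under bin-mean resampling).

    ``hyp_amplitude`` is expressed in the analysis' own measurement
    convention, set by ``depth_reference``:

    - ``"baseline"`` (default): the amplitude a slow-Gaussian-baseline
      measurement (sigma ``baseline_sigma``) recovers on the noiseless
      trace — i.e. the hyperpolarization amplitude as the downstream
      analysis defines it; the raw trough below resting is deeper, because
      the baseline itself sags with the oscillation's mean.
    - ``"trough"``: the plain trough depth below ``resting_vm``.
    """

    resting_vm: float = -50.0  # mV
    hyp_amplitude: float = 4.0  # mV
    osc_smoothness: float = 0.5  # s
    noise_sd: float = 1.5  # mV
    noise_tau: float = 0.15  # s
    drift: float = 0.0  # mV/min
    depth_reference: str = "baseline"
    baseline_sigma: float = 5.0  # s, reference for the baseline convention

    def validate(self) -> None:
        if self.hyp_amplitude < 0:
            raise ValueError("hyp_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.osc_smoothness < 0:
            raise ValueError("osc_smoothness must be >= 0")
        if self.noise_tau <= 0:
            raise ValueError("noise_tau must be > 0")
        if self.depth_reference not in ("baseline", "trough"):
            raise ValueError(f"unknown depth_reference {self.depth_reference!r}")
        if self.baseline_sigma <= 0:
            raise ValueError("baseline_sigma must be > 0")


@dataclass(frozen=True)
class KinematicSpec:
    """Crawling-step kinematics of a 9-point dorsal-midline track.

    Each step is iso_pre → elongation → contraction → iso_post: the two
    isometric stages flank the contiguous dynamic gesture, whose maximum
    section length separates elongation from contraction.  All eight body
    sections move synchronously (no intersegmental lag is modelled).
    Fractions are of the step duration and must sum to 1.
    """

    step_duration: float = 7.49  # s
    elong_frac: float = 0.325
    contr_frac: float = 0.175
    iso_pre_frac: float = 0.38
    iso_post_frac: float = 0.12
    section_rest_length: float = 10.0  # mm
    elongation_gain: float = 0.6  # peak length = rest * (1 + gain)
    fps: float = 60.0
    noise_sd: float = 0.2  # mm, per-coordinate tracking jitter
    n_steps: int = 20
    creep_speed: float = 0.5  # mm/s peak whole-body progression inside a step
    ramp_blend_s: float = 0.1  # accel time (s) at gesture onsets/offsets
    turn_time_s: float = 0.3  # time-symmetric elongation->contraction turnaround (s)

    def validate(self) -> None:
        fracs = (
            self.elong_frac,
            self.contr_frac,
            self.iso_pre_frac,
            self.iso_post_frac,
        )
        if any(f < 0 for f in fracs):
            raise ValueError("phase fractions must be >= 0")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"phase fractions must sum to 1, got {sum(fracs)}")
        if not self.fps > 0:
            raise ValueError("fps must be > 0")
        if not self.step_duration > 0:
            raise ValueError("step_duration must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def dynamic_duty_elong(self) -> float:
        """Programmed elongation fraction of the dynamic (elong+contr) step."""
        return self.elong_frac / (self.elong_frac + self.contr_frac)


def make_template(
    amplitude: float,
    width_ms: float = 1.0,
    rate: float = 10_000.0,
    polarity: int = -1,
    asymmetry: float = 0.5,
) -> np.ndarray:
    """Biphasic extracellular spike template sampled at ``rate``.

    A difference of two Gaussian lobes: the leading lobe has sign
    ``polarity`` and peak ``amplitude``; the trailing lobe is
    ``asymmetry`` times smaller and opposite in sign.  Total support is
    about 4x ``width_ms``.
    """
    if amplitude <= 0:
        raise ValueError("template amplitude must be > 0")
    w = width_ms * 1e-3
    half = int(round(2.0 * w * rate))
    t = (np.arange(2 * half + 1) - half) / rate
    lobe1 = np.exp(-0.5 * ((t + 0.35 * w) / (0.35 * w)) ** 2)
    lobe2 = np.exp(-0.5 * ((t - 0.55 * w) / (0.5 * w)) ** 2)
    shape = polarity * (lobe1 - asymmetry * lobe2)
    return amplitude * shape / np.max(np.abs(shape))
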