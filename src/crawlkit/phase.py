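"""Per-unit phase tuning across crawling cycles.

Maps each unit's spikes to normalized cycle phase (start-to-start
segmentation, phase = (t - cycle start) / period), averages binned firing
frequency over cycles into a phase profile, tests rhythmicity via the bFF
autocorrelogram, classifies units relative to the DE-3 window (in-phase /
anti-phase / in-phase-early-onset) and extracts Max bFF, relative
half-width and onset phase per profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rhythm import RateCurve

__all__ = [
    "PhaseProfile",
    "RhythmicityResult",
    "autocorr_rhythmicity",
    "phase_profile",
    "classify_unit",
    "profile_metrics",
    "epoch_profiles",
]


@dataclass
class PhaseProfile:
    """Mean binned firing rate versus normalized cycle phase for one unit."""

    unit_id: str
    phases: np.ndarray  # bin centers, fractions in [0, 1)
    mean_bff: np.ndarray  # Hz, averaged over cycles
    n_cycles: int
    max_bff: float | None = None
    rel_hw: float | None = None
    onset_phase: float | None = None
    label: str | None = None
    flag: str | None = None  # e.g. "silent"

    @property
    def n_bins(self) -> int:
        return self.phases.size


@dataclass
class RhythmicityResult:
    """Autocorrelogram-based rhythmicity test for one unit."""

    unit_id: str
    lags: np.ndarray  # s
    coefficients: np.ndarray  # Pearson r at each lag
    n_qualifying_peaks: int
    is_rhythmic: bool
    flag: str | None = None


def _pearson_at_lag(x: np.ndarray, k: int) -> float:
    a, b = x[: x.size - k], x[k:]
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def autocorr_rhythmicity(
    bff: RateCurve,
    period: float,
    n_cycles: int = 4,
    min_peaks: int = 2,
    min_r: float = 0.25,
    unit_id: str = "",
) -> RhythmicityResult:
    """Rhythmicity test on the bFF of the first ``n_cycles`` cycles.

    Pearson autocorrelation at every lag up to ~2 periods; non-zero-lag
    local maxima exceeding ``min_r`` are counted (requiring at least half a
    period between qualifying peaks); the unit is rhythmic when the count
    reaches ``min_peaks``.  Because the overlap shrinks with lag, a peak
    must also clear the white-noise significance floor 2.5 / sqrt(overlap)
    — otherwise short windows routinely produce chance maxima above the
    fixed criterion.  A constant bFF has no defined autocorrelation and is
    reported non-rhythmic with a flag.
    """
    dt = bff.bin_width
    n_win = min(int(round(n_cycles * period / dt)), bff.values.size)
    x = bff.values[:n_win]
    # a hair beyond two periods so the second rhythmic peak (at ~2T, jittered)
    # is an interior local maximum rather than a boundary sample
    max_lag = min(int(round(2.5 * period / dt)), x.size - 2)
    if max_lag < 1 or np.std(x) == 0:
        return RhythmicityResult(
            unit_id, np.empty(0), np.empty(0), 0, False, flag="constant"
        )
    lags_k = np.arange(max_lag + 1)
    r = np.array([1.0] + [_pearson_at_lag(x, int(k)) for k in lags_k[1:]])

    min_sep = max(int(round(0.5 * period / dt)), 1)
    peaks = []
    for k in range(1, max_lag):
        floor = max(min_r, 2.5 / np.sqrt(x.size - k))
        if np.isnan(r[k]) or r[k] <= floor:
            continue
        if r[k] >= r[k - 1] and r[k] >= r[k + 1]:
            if not peaks or k - peaks[-1] >= min_sep:
                peaks.append(k)
    return RhythmicityResult(
        unit_id=unit_id,
        lags=lags_k * dt,
        coefficients=r,
        n_qualifying_peaks=len(peaks),
        is_rhythmic=len(peaks) >= min_peaks,
    )


def phase_profile(
    spikes: np.ndarray,
    cycles: pd.DataFrame,
    n_bins: int = 50,
    n_cycles: int | None = 4,
    unit_id: str = "",
) -> PhaseProfile:
    """Mean bFF versus cycle phase over the first ``n_cycles`` cycles.

    Each cycle's spikes map to phase (t - start)/period and are binned at
    that cycle's own bin duration (period / n_bins); bins are then averaged
    across cycles.  ``n_cycles=None`` uses every cycle in the table.  A unit
    silent in all cycles yields an all-zero profile flagged ``"silent"``.
    """
    if cycles.attrs.get("mode", "start_to_start") != "start_to_start":
        warnings.warn("phase profiles assume start-to-start segmentation")
    spikes = np.asarray(spikes, dtype=float)
    use = cycles if n_cycles is None else cycles.iloc[:n_cycles]
    if len(use) == 0:
        raise ValueError("no cycles available for the phase profile")
    if n_cycles is not None and len(use) < n_cycles:
        warnings.warn(f"only {len(use)} cycles available (requested {n_cycles})")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rates = np.zeros((len(use), n_bins))
    for i, (_, row) in enumerate(use.iterrows()):
        period = row["period_s"]
        sel = spikes[(spikes >= row["start"]) & (spikes < row["end"])]
        phase = (sel - row["start"]) / period
        counts, _ = np.histogram(phase, bins=edges)
        rates[i] = counts / (period / n_bins)
    mean_bff = rates.mean(axis=0)
    prof = PhaseProfile(
        unit_id=unit_id,
        phases=0.5 * (edges[:-1] + edges[1:]),
        mean_bff=mean_bff,
        n_cycles=len(use),
        flag="silent" if not np.any(mean_bff > 0) else None,
    )
    return prof


def _smooth_circular(y: np.ndarray, sigma_bins: float) -> np.ndarray:
    if sigma_bins <= 0:
        return y
    from scipy.ndimage import gaussian_filter1d

    return gaussian_filter1d(y, sigma_bins, mode="wrap")


def _cross_backward(y: np.ndarray, start: int, thresh: float) -> float | None:
    """Continuous circular position where ``y`` drops below ``thresh``,
    walking backward from index ``start``; None if it never does."""
    n = y.size
    for step in range(1, n + 1):
        j = (start - step) % n
        jn = (j + 1) % n
        if y[j] < thresh:
            frac = (thresh - y[j]) / (y[jn] - y[j]) if y[jn] != y[j] else 1.0
            return (start - step + frac) % n
    return None


def _cross_forward(y: np.ndarray, start: int, thresh: float) -> float | None:
    n = y.size
    for step in range(1, n + 1):
        j = (start + step) % n
        jp = (j - 1) % n
        if y[j] < thresh:
            frac = (y[jp] - thresh) / (y[jp] - y[j]) if y[jp] != y[j] else 0.0
            return (start + step - 1 + frac) % n
    return None


def profile_metrics(
    profile: PhaseProfile,
    onset_baseline_frac: float = 0.2,
    smooth_sigma_bins: float = 2.0,
) -> tuple[float, float, float]:
    """(max_bff, rel_hw, onset_phase) of a nonzero phase profile.

    The profile is lightly smoothed on the circle first (symmetric Gaussian
    of ``smooth_sigma_bins`` bins — this leaves the half-maximum crossings
    of a step edge in place, so a rectangle's width is measured exactly).
    rel_hw is the circular width at half maximum around the peak, with the
    crossings linearly interpolated between bins; the onset phase is the
    interpolated crossing of ``onset_baseline_frac`` x max found walking
    backward from the peak.  All three are attached to the profile.
    """
    y0 = profile.mean_bff
    if not np.any(y0 > 0):
        profile.flag = "silent"
        raise ValueError("metrics undefined for an all-zero profile")
    n = y0.size
    y = _smooth_circular(y0, smooth_sigma_bins)
    max_bff = float(y.max())
    peak = int(np.argmax(y))
    half = max_bff / 2.0
    left = _cross_backward(y, peak, half)
    right = _cross_forward(y, peak, half)
    if left is None or right is None:
        rel_hw = 1.0  # never drops below half anywhere: full-cycle activity
    else:
        # crossings are in bin-center coordinates, so the difference is the
        # width in bins (a step edge lands exactly halfway between bins)
        width_bins = (right - left) % n
        rel_hw = min(width_bins / n, 1.0)

    thresh = onset_baseline_frac * max_bff
    onset = _cross_backward(y, peak, thresh)
    onset_phase = 0.0 if onset is None else float(((onset + 0.5) % n) / n)

    profile.max_bff = max_bff
    profile.rel_hw = float(rel_hw)
    profile.onset_phase = onset_phase
    return max_bff, float(rel_hw), onset_phase


def _circular_center(phases: np.ndarray) -> float:
    ang = 2.0 * np.pi * phases
    c = np.mean(np.cos(ang))
    s = np.mean(np.sin(ang))
    return float((np.arctan2(s, c) / (2.0 * np.pi)) % 1.0)


def classify_unit(
    profile: PhaseProfile,
    de3_duty: float,
    onset_tol: float = 0.05,
    onset_baseline_frac: float = 0.2,
    smooth_sigma_bins: float = 2.0,
    bimodal_height_frac: float = 0.9,
) -> str:
    """Deterministic phase-class label for a rhythmic unit's profile.

    The peak location is the circular center of the half-maximum region
    (robust to flat-topped profiles that straddle the cycle wrap).  Peak
    inside the DE-3 window with onset no earlier than ``onset_tol`` before
    cycle start -> ``in_phase``; same peak but onset wrapped earlier ->
    ``in_phase_early_onset``; peak in the interburst window -> ``anti_phase``.
    Profiles with two comparable, well-separated peaks are ``unclassified``.
    """
    y0 = profile.mean_bff
    if not np.any(y0 > 0):
        profile.label = "unclassified"
        return "unclassified"
    max_bff, rel_hw, onset = profile_metrics(
        profile, onset_baseline_frac, smooth_sigma_bins
    )
    n = y0.size
    y = _smooth_circular(y0, smooth_sigma_bins)
    peak = int(np.argmax(y))
    half = max_bff / 2.0
    left = _cross_backward(y, peak, half)
    right = _cross_forward(y, peak, half)

    if left is None or right is None:
        peak_phase = float((peak + 0.5) / n)
    else:
        width = (right - left) % n
        peak_phase = float((((left + width / 2.0) % n) + 0.5) / n)
        # bimodality guard: a second local maximum comparable to the peak
        # outside the primary half-max region
        inside = ((np.arange(n) - left) % n) <= width + 1
        for k in range(n):
            if inside[k]:
                continue
            if (
                y[k] >= y[(k - 1) % n]
                and y[k] >= y[(k + 1) % n]
                and y[k] >= bimodal_height_frac * max_bff
            ):
                profile.label = "unclassified"
                return "unclassified"

    if peak_phase < de3_duty:
        # onset "before cycle start" shows up wrapped near 1
        if onset > 0.5 and onset < 1.0 - onset_tol:
            label = "in_phase_early_onset"
        else:
            label = "in_phase"
    else:
        label = "anti_phase"
    profile.label = label
    return label


def epoch_profiles(
    spikes: np.ndarray,
    cycles: pd.DataFrame,
    n_bins: int = 50,
    unit_id: str = "",
    onset_baseline_frac: float = 0.2,
) -> dict[str, PhaseProfile]:
    """One phase profile per epoch (pre/test/post) with metrics attached.

    Each epoch's profile averages only that epoch's cycles.  Epochs with no
    cycles are reported missing (absent from the dict); silent profiles are
    flagged but still returned.
    """
    out: dict[str, PhaseProfile] = {}
    for epoch in ("pre", "test", "post"):
        sub = cycles[cycles["epoch"] == epoch]
        if len(sub) == 0:
            continue
        prof = phase_profile(
            spikes, sub, n_bins=n_bins, n_cycles=None, unit_id=unit_id
        )
        if prof.flag != "silent":
            profile_metrics(prof, onset_baseline_frac)
        out[epoch] = prof
    return out
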