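"""NS membrane-potential structure relative to DE-3 activity.

Resamples the intracellular trace onto the DE-3 bFF grid (bin means),
cross-correlates the two signals (Pearson per lag on the overlap, so
coefficients are bounded in [-1, 1]), extracts a slow Gaussian baseline,
and measures the per-burst hyperpolarization amplitude: baseline potential
at the first spike of a DE-3 burst minus the minimum potential during that
burst.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .rhythm import Burst, RateCurve
from .timeseries import TimeSeries

__all__ = [
    "Correlogram",
    "resample_trace",
    "cross_correlate",
    "ns_baseline",
    "hyp_amplitude",
    "feature_table",
]


@dataclass
class Correlogram:
    """Pearson cross-correlation versus lag, with its extremum.

    The peak is the extremum by absolute value (convention recorded in
    ``peak_convention``); positive lag means the second input trails the
    first.
    """

    lags: np.ndarray  # s, symmetric
    coefficients: np.ndarray
    peak_coefficient: float
    peak_lag: float
    peak_convention: str = "max_abs"
    peak_range: float | None = None  # lag window searched for the peak


def resample_trace(vm: TimeSeries, target: RateCurve) -> TimeSeries:
    """Bin-mean resample of ``vm`` onto the bins of ``target``.

    One value per bFF bin (anti-aliasing mean of the samples falling in the
    bin); output rate is 1 / bin width.  Rejected if the trace does not
    overlap the target span.
    """
    edges = target.edges
    t = vm.times
    if t[-1] < edges[0] or t[0] > edges[-1]:
        raise ValueError("trace does not overlap the target span")
    idx = np.searchsorted(edges, t, side="right") - 1
    ok = (idx >= 0) & (idx < target.values.size)
    sums = np.bincount(idx[ok], weights=vm.values[ok], minlength=target.values.size)
    counts = np.bincount(idx[ok], minlength=target.values.size)
    out = np.full(target.values.size, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    # bins not covered by the trace inherit their nearest covered neighbour
    if np.any(~nz):
        covered = np.flatnonzero(nz)
        if covered.size == 0:
            raise ValueError("trace does not overlap the target span")
        nearest = covered[
            np.argmin(np.abs(np.arange(out.size)[:, None] - covered[None, :]), axis=1)
        ]
        out[~nz] = out[nearest[~nz]]
    return TimeSeries(
        out, rate=1.0 / target.bin_width, units=vm.units, t0=float(target.centers[0])
    )


def cross_correlate(
    x: TimeSeries, y: TimeSeries, max_lag: float, peak_range: float | None = None
) -> Correlogram:
    """Pearson coefficient per lag over the overlapping window.

    Requires equal sampling grids.  The correlogram covers lags in
    [-max_lag, +max_lag]; the reported peak is the extremum by absolute
    value within ``peak_range`` (default: half of ``max_lag``).  With
    ``max_lag`` set to one cycle period this confines the peak to the
    fundamental domain — for periodic signals the side lobes at ±T are
    copies of the lag-0 structure and carry no extra timing information.
    A zero-variance input is rejected.
    """
    if peak_range is None:
        peak_range = max_lag / 2.0
    if abs(x.rate - y.rate) > 1e-9 * x.rate:
        raise ValueError("inputs must share one sampling grid")
    a, b = x.values, y.values
    n = min(a.size, b.size)
    a, b = a[:n], b[:n]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    kmax = min(int(round(max_lag * x.rate)), n - 2)
    lags_k = np.arange(-kmax, kmax + 1)
    r = np.empty(lags_k.size)
    for i, k in enumerate(lags_k):
        if k >= 0:
            u, v = a[: n - k], b[k:]
        else:
            u, v = a[-k:], b[: n + k]
        if u.size < 2 or np.std(u) == 0 or np.std(v) == 0:
            r[i] = np.nan
        else:
            r[i] = np.corrcoef(u, v)[0, 1]
    # extremum by |r| inside the peak window; ties toward the smaller |lag|
    in_range = np.abs(lags_k / x.rate) <= peak_range + 1e-12
    cand = np.flatnonzero(np.isfinite(r) & in_range)
    if cand.size == 0:
        cand = np.flatnonzero(np.isfinite(r))
    best = cand[np.lexsort((np.abs(lags_k[cand]), -np.abs(r[cand])))][0]
    return Correlogram(
        lags=lags_k / x.rate,
        coefficients=r,
        peak_coefficient=float(r[best]),
        peak_lag=float(lags_k[best] / x.rate),
        peak_range=float(peak_range),
    )


def ns_baseline(vm: TimeSeries, sigma: float = 5.0) -> TimeSeries:
    """Slow baseline via a heavy Gaussian filter (default sigma 5 s).

    Same grid as the input; rejected when the trace is shorter than the
    kernel support (~4 sigma).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if vm.duration < 4.0 * sigma:
        raise ValueError(
            f"trace ({vm.duration:.1f} s) shorter than kernel support ({4 * sigma:.0f} s)"
        )
    return vm.with_values(gaussian_filter1d(vm.values, sigma * vm.rate, mode="reflect"))


def hyp_amplitude(
    vm: TimeSeries,
    baseline: TimeSeries,
    bursts: list[Burst],
    trough_smooth: float = 0.25,
) -> pd.DataFrame:
    """Per-burst NS hyperpolarization amplitude.

    amplitude = baseline(t of the burst's first spike, nearest sample)
    minus the minimum membrane potential during [first, last spike].  The
    trace is lightly smoothed (``trough_smooth`` seconds, default 0.25 s)
    before taking the minimum so sample-level noise does not bias the
    trough downward; the hyperpolarization itself is much slower than the
    kernel.  A negative amplitude (no hyperpolarization) is kept but
    flagged.  Bursts outside the trace span are skipped with a warning.
    """
    if trough_smooth > 0 and vm.duration > 8 * trough_smooth:
        vm = vm.with_values(
            gaussian_filter1d(vm.values, trough_smooth * vm.rate, mode="reflect")
        )
    rows = []
    t_lo, t_hi = vm.t0, vm.t0 + vm.duration
    for i, b in enumerate(bursts):
        if b.first_spike < t_lo or b.last_spike > t_hi:
            warnings.warn(f"burst {i} outside trace span; skipped")
            continue
        base = float(baseline.values[baseline.index_at(b.first_spike)])
        seg = vm.slice(b.first_spike, b.last_spike)
        if seg.n == 0:
            warnings.warn(f"burst {i} covers no samples; skipped")
            continue
        vmin = float(seg.values.min())
        amp = base - vmin
        rows.append(
            {
                "burst": i,
                "t_first_spike": b.first_spike,
                "baseline_mv": base,
                "min_mv": vmin,
                "amplitude_mv": amp,
                "no_hyperpolarization": amp < 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "burst",
            "t_first_spike",
            "baseline_mv",
            "min_mv",
            "amplitude_mv",
            "no_hyperpolarization",
        ],
    )


def feature_table(amplitudes: pd.DataFrame, bursts: list[Burst]) -> pd.DataFrame:
    """Per-cycle export pairing hyperpolarization amplitude with burst metrics.

    One row per measured burst: amplitude, the burst's mFF and duration, and
    the interburst intervals preceding and following it (NaN at the
    recording edges) — the covariates of the mixed-model regressions run
    downstream.
    """
    if len(amplitudes) and amplitudes["burst"].max() >= len(bursts):
        raise ValueError("amplitude table refers to bursts that do not exist")
    rows = []
    for _, arow in amplitudes.iterrows():
        i = int(arow["burst"])
        b = bursts[i]
        pre = b.first_spike - bursts[i - 1].last_spike if i > 0 else np.nan
        post = (
            bursts[i + 1].first_spike - b.last_spike if i + 1 < len(bursts) else np.nan
        )
        rows.append(
            {
                "cycle": i,
                "amplitude_mv": arow["amplitude_mv"],
                "burst_mff_hz": b.mff,
                "burst_duration_s": b.duration,
                "pre_interburst_s": pre,
                "post_interburst_s": post,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cycle",
            "amplitude_mv",
            "burst_mff_hz",
            "burst_duration_s",
            "pre_interburst_s",
            "post_interburst_s",
        ],
    )
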