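"""Behavioral crawling analysis from 9-point pose-tracking tables.

Pipeline: parse the tracking table (DeepLabCut 3-row-header dialect or the
flat synthetic CSV), compute per-section lengths (Euclidean distance
between adjacent dorsal-midline points, Gaussian-smoothed), segment the
bout into steps at minima of a combined body-length/endpoint-velocity
score, locate elongation/contraction boundaries per step (maximum section
length plus knee points on the rising and falling limbs), and summarize
behavioral duty cycles over the dynamic (elongation + contraction) part of
each step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

__all__ = [
    "PoseTrack",
    "load_pose",
    "section_lengths",
    "segment_steps",
    "kneedle",
    "phase_boundaries",
    "step_table",
    "behavioral_duty",
]

N_POINTS = 9

STEP_COLUMNS = [
    "step",
    "t_start",
    "t_end",
    "elong_s",
    "contr_s",
    "iso_pre_s",
    "iso_post_s",
    "duty_elong",
    "duty_contr",
    "qc",
]


@dataclass
class PoseTrack:
    """A 9-point tracked bout: positions, likelihoods, validity per frame."""

    points: np.ndarray  # (n, 9, 2)
    likelihood: np.ndarray  # (n, 9)
    fps: float
    valid: np.ndarray  # (n,) frames where every point passes the floor

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


def load_pose(
    path,
    fps: float = 60.0,
    likelihood_floor: float = 0.9,
    px_to_mm: float | None = None,
) -> PoseTrack:
    """Parse a pose-tracking table into a :class:`PoseTrack`.

    Accepts the DeepLabCut CSV dialect (3 header rows: scorer / bodyparts /
    coords with x, y, likelihood per point) or the flat synthetic export
    (``point{i}_x`` / ``point{i}_y`` columns, likelihood assumed 1).
    Frames with any point below ``likelihood_floor`` are marked invalid.
    Tables with a point count other than 9, or fewer than 2 frames, are
    rejected.  ``px_to_mm`` rescales pixel coordinates when given.
    """
    with open(path) as fh:
        first = fh.readline()
        second = fh.readline()
    if "bodyparts" in first or "bodyparts" in second:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        bodyparts = list(dict.fromkeys(c[1] for c in df.columns))
        if len(bodyparts) != N_POINTS:
            raise ValueError(f"expected {N_POINTS} tracked points, got {len(bodyparts)}")
        n = len(df)
        pts = np.empty((n, N_POINTS, 2))
        lik = np.ones((n, N_POINTS))
        scorer = df.columns[0][0]
        for j, bp in enumerate(bodyparts):
            pts[:, j, 0] = df[(scorer, bp, "x")].to_numpy()
            pts[:, j, 1] = df[(scorer, bp, "y")].to_numpy()
            if (scorer, bp, "likelihood") in df.columns:
                lik[:, j] = df[(scorer, bp, "likelihood")].to_numpy()
    else:
        df = pd.read_csv(path)
        xcols = [c for c in df.columns if c.endswith("_x") and c.startswith("point")]
        if len(xcols) != N_POINTS:
            raise ValueError(f"expected {N_POINTS} tracked points, got {len(xcols)}")
        n = len(df)
        pts = np.empty((n, N_POINTS, 2))
        lik = np.ones((n, N_POINTS))
        for j in range(N_POINTS):
            pts[:, j, 0] = df[f"point{j + 1}_x"].to_numpy()
            pts[:, j, 1] = df[f"point{j + 1}_y"].to_numpy()
    if n < 2:
        raise ValueError("need at least 2 frames")
    if px_to_mm is not None:
        pts = pts * px_to_mm
    valid = np.all(lik >= likelihood_floor, axis=1)
    return PoseTrack(points=pts, likelihood=lik, fps=fps, valid=valid)


def _interpolate_invalid(x: np.ndarray, valid: np.ndarray, gap_limit: int) -> np.ndarray:
    """Linearly bridge invalid runs up to ``gap_limit`` frames long."""
    if valid.all():
        return x
    out = x.copy()
    idx = np.arange(x.shape[0])
    bad = ~valid
    # find runs of invalid frames
    edges = np.flatnonzero(np.diff(np.r_[0, bad.view(np.int8), 0]))
    for lo, hi in zip(edges[::2], edges[1::2]):
        if hi - lo <= gap_limit and lo > 0 and hi < x.shape[0]:
            out[lo:hi] = np.interp(idx[lo:hi], [lo - 1, hi], [x[lo - 1], x[hi]])
    return out


def section_lengths(
    track: PoseTrack, sigma: float = 0.25, gap_limit: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame section lengths and total body length, smoothed.

    Sections are the 8 adjacent point pairs; lengths are Gaussian-filtered
    with ``sigma`` seconds.  Invalid frames are interpolated across gaps up
    to ``gap_limit`` frames; longer gaps stay invalid (steps touching them
    are later discarded).  Returns ``(sections (n, 8), total (n,))``.
    """
    d = np.diff(track.points, axis=1)  # (n, 8, 2)
    lengths = np.sqrt(np.sum(d * d, axis=2))
    for s in range(lengths.shape[1]):
        lengths[:, s] = _interpolate_invalid(lengths[:, s], track.valid, gap_limit)
    if sigma > 0:
        lengths = gaussian_filter1d(lengths, sigma * track.fps, axis=0, mode="reflect")
    total = lengths.sum(axis=1)
    return lengths, total


def endpoint_speeds(track: PoseTrack, sigma: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """|v| of the most anterior and most posterior points (mm/s).

    Central differences on Gaussian-smoothed positions; magnitude of the
    2-D velocity vector.
    """
    speeds = []
    for j in (0, N_POINTS - 1):
        p = track.points[:, j, :].copy()
        if sigma > 0:
            p = gaussian_filter1d(p, sigma * track.fps, axis=0, mode="reflect")
        v = np.gradient(p, 1.0 / track.fps, axis=0)
        speeds.append(np.sqrt(np.sum(v * v, axis=1)))
    return speeds[0], speeds[1]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    return (x - np.mean(x)) / sd if sd > 0 else np.zeros_like(x)


def segment_steps(
    total_length: np.ndarray,
    anterior_speed: np.ndarray,
    posterior_speed: np.ndarray,
    fps: float,
    min_separation: float = 2.0,
    valid: np.ndarray | None = None,
    min_prominence: float = 0.5,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Step boundaries at minima of the combined unit-free score.

    The score is the sum of the z-scored body length and the two z-scored
    endpoint speeds (z-scoring makes mm and mm/s commensurable); boundaries
    are its local minima separated by at least ``min_separation`` seconds,
    edges included.  Minima where the body length is above its episode mean
    are rejected: the animal also pauses momentarily at full extension
    (end of elongation), and that lull is not a step boundary.  Minima
    must have a prominence of at least ``min_prominence`` (in z-score
    units), which keeps tracking noise inside the between-step lull from
    splitting a step.  Steps
    containing frames marked invalid are discarded.
    Returns ``(boundary indices, list of (start, end) step index pairs)``.
    """
    z_len = _zscore(total_length)
    score = z_len + _zscore(anterior_speed) + _zscore(posterior_speed)
    dist = max(int(round(min_separation * fps)), 1)
    padded = np.r_[score[0] + 10.0, score, score[-1] + 10.0]
    peaks, _ = find_peaks(-padded, distance=dist, prominence=min_prominence)
    boundaries = np.clip(peaks - 1, 0, score.size - 1)
    boundaries = boundaries[z_len[boundaries] < 0]
    if boundaries.size < 2:
        warnings.warn("no step boundaries found")
        return boundaries, []
    steps = []
    for i0, i1 in zip(boundaries[:-1], boundaries[1:]):
        if valid is not None and not np.all(valid[i0 : i1 + 1]):
            continue
        steps.append((int(i0), int(i1)))
    return boundaries, steps


def kneedle(y: np.ndarray, sensitivity: float = 1.0) -> int | None:
    """Knee index of a sampled monotone segment.

    Normalizes both axes to [0, 1], orients the curve to be increasing,
    and returns the index maximizing the deviation between the curve and
    the chord joining its endpoints (on the convex side the deviation
    ``chord - curve``, on the concave side ``curve - chord``).  Returns
    ``None`` when the maximum deviation is below ``sensitivity`` sample
    spacings (a straight line has no knee).  The result is invariant to
    affine transforms of either axis.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 5:
        raise ValueError("need at least 5 samples")
    flipped = y[-1] < y[0]
    yy = y[::-1] if flipped else y
    rng_y = yy[-1] - yy[0]
    if rng_y == 0:
        return None
    x_n = np.linspace(0.0, 1.0, n)
    y_n = (yy - yy[0]) / rng_y
    d = y_n - x_n
    # concave curves bow above the chord, convex below
    if np.abs(d.max()) >= np.abs(d.min()):
        k, dev = int(np.argmax(d)), float(d.max())
    else:
        k, dev = int(np.argmin(d)), float(-d.min())
    if dev < sensitivity / (n - 1):
        return None
    return (n - 1 - k) if flipped else k


def phase_boundaries(
    section: np.ndarray,
    step: tuple[int, int],
    fps: float,
    sensitivity: float = 1.0,
) -> tuple[int, int, int] | None:
    """(elongation onset, max-length, contraction end) frames within a step.

    The maximum section length separates elongation from contraction; the
    elongation onset is the knee of the rising limb (step start -> max) and
    the contraction end the knee of the falling limb (max -> step end).
    Returns ``None`` (step unusable) when the maximum sits at a step edge
    (monotone trace) or either knee is undefined.
    """
    i0, i1 = step
    seg = section[i0 : i1 + 1]
    imax = int(np.argmax(seg))
    if imax <= 1 or imax >= seg.size - 2:
        return None
    rise, fall = seg[: imax + 1], seg[imax:]
    if rise.size < 5 or fall.size < 5:
        return None
    k_r = kneedle(rise, sensitivity)
    k_f = kneedle(fall, sensitivity)
    if k_r is None or k_f is None:
        return None
    return i0 + k_r, i0 + imax, i0 + imax + k_f


def step_table(
    section: np.ndarray,
    steps: list[tuple[int, int]],
    fps: float,
    sensitivity: float = 1.0,
) -> pd.DataFrame:
    """Per-step phase durations and behavioral duty cycles for one section.

    duty_elong = elongation / (elongation + contraction) over the dynamic
    step; isometric stages are excluded from the duty by construction, so
    duty_elong + duty_contr = 1 exactly for usable steps.
    """
    rows = []
    for s, (i0, i1) in enumerate(steps):
        pb = phase_boundaries(section, (i0, i1), fps, sensitivity)
        if pb is None:
            rows.append(
                dict.fromkeys(STEP_COLUMNS)
                | {"step": s, "t_start": i0 / fps, "t_end": i1 / fps, "qc": "unusable"}
            )
            continue
        on, mx, end = pb
        elong = (mx - on) / fps
        contr = (end - mx) / fps
        dyn = elong + contr
        if dyn <= 0:
            rows.append(
                dict.fromkeys(STEP_COLUMNS)
                | {"step": s, "t_start": i0 / fps, "t_end": i1 / fps, "qc": "zero_dynamic"}
            )
            continue
        rows.append(
            {
                "step": s,
                "t_start": i0 / fps,
                "t_end": i1 / fps,
                "elong_s": elong,
                "contr_s": contr,
                "iso_pre_s": (on - i0) / fps,
                "iso_post_s": (i1 - end) / fps,
                "duty_elong": elong / dyn,
                "duty_contr": contr / dyn,
                "qc": "ok",
            }
        )
    return pd.DataFrame(rows, columns=STEP_COLUMNS)


def behavioral_duty(steps: pd.DataFrame) -> dict:
    """Per-animal summary of usable steps: duty cycles and step duration."""
    ok = steps[steps["qc"] == "ok"]
    if len(ok) == 0:
        raise ValueError("no usable steps")
    dur = ok["t_end"] - ok["t_start"]
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan
    return {
        "n_steps": int(len(ok)),
        "duty_elong_mean": float(ok["duty_elong"].mean()),
        "duty_elong_sem": sem(ok["duty_elong"]),
        "duty_contr_mean": float(ok["duty_contr"].mean()),
        "duty_contr_sem": sem(ok["duty_contr"]),
        "step_duration_mean_s": float(dur.mean()),
        "step_duration_sem_s": sem(dur),
    }
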