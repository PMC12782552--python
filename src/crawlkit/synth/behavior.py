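"""Synthetic crawling kinematics: a 9-point dorsal-midline track.

Each step is iso_pre -> elongation -> contraction -> iso_post; the maximum
section length is the elongation/contraction boundary and the isometric
stages flank the dynamic gesture.  The animal advances by anchoring its
rear during elongation and its front during contraction, plus a small
smooth whole-body progression whose speed vanishes exactly at step
boundaries — so the combined length/endpoint-velocity score used by step
segmentation has a unique minimum at each true boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ground_truth import GroundTruth
from .specs import KinematicSpec

__all__ = ["BehaviorRecording", "gen_behavior"]

N_POINTS = 9
N_SECTIONS = 8


@dataclass
class BehaviorRecording:
    """Per-frame synthetic pose track with its generating ground truth."""

    fps: float
    points: np.ndarray  # (n_frames, 9, 2) in mm
    likelihood: np.ndarray  # (n_frames, 9)
    section_lengths: np.ndarray  # (n_frames, 8), noiseless programmed lengths
    total_length: np.ndarray  # (n_frames,)
    truth: GroundTruth
    spec: KinematicSpec

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def to_dlc_csv(self, path: str | Path, scorer: str = "synthetic") -> None:
        """Write the track in the DeepLabCut 3-row-header CSV dialect."""
        cols = []
        data = {}
        for j in range(N_POINTS):
            bp = f"point{j + 1}"
            for coord, arr in (
                ("x", self.points[:, j, 0]),
                ("y", self.points[:, j, 1]),
                ("likelihood", self.likelihood[:, j]),
            ):
                cols.append((scorer, bp, coord))
                data[(scorer, bp, coord)] = arr
        df = pd.DataFrame(data)
        df.columns = pd.MultiIndex.from_tuples(
            cols, names=["scorer", "bodyparts", "coords"]
        )
        df.to_csv(path)

    def to_csv(self, path: str | Path) -> None:
        """Flat CSV: frame, time_s, point_i_x/y, section lengths, total."""
        out = {"frame": np.arange(self.n_frames), "time_s": self.times}
        for j in range(N_POINTS):
            out[f"point{j + 1}_x"] = self.points[:, j, 0]
            out[f"point{j + 1}_y"] = self.points[:, j, 1]
        for s in range(N_SECTIONS):
            out[f"section_{s + 1}_{s + 2}_mm"] = self.section_lengths[:, s]
        out["total_length_mm"] = self.total_length
        pd.DataFrame(out).to_csv(path, index=False)


def _trapezoid_speed(t: np.ndarray, T: float, rise: float, fall: float) -> np.ndarray:
    """Unit-plateau trapezoidal speed profile on [0, T]."""
    v = np.ones_like(t)
    v = np.where(t < rise, t / rise, v)
    v = np.where(t > T - fall, (T - t) / fall, v)
    return np.clip(v, 0.0, 1.0)


def _step_profile(u: np.ndarray, spec: KinematicSpec) -> np.ndarray:
    """Normalized section-length excursion s(u) in [0, 1] for phase u of a step.

    Built from piecewise-linear speed profiles.  The gesture accelerates
    over ``ramp_blend_s`` (crisp onsets, as in real section traces), and
    the elongation->contraction turnaround is *time-symmetric*: over the
    shared ``turn_time_s`` the contraction speed is the mirror image of the
    elongation deceleration, after which it accelerates to the higher rate
    the shorter contraction needs.  The smoothed trace therefore peaks at
    the programmed junction rather than drifting toward the shallower limb.
    """
    T = spec.step_duration
    Te = spec.elong_frac * T
    Tc = spec.contr_frac * T
    beta = min(spec.ramp_blend_s, 0.3 * min(Te, Tc))
    tau = min(spec.turn_time_s, 0.4 * min(Te, Tc))
    beta2 = min(0.2 * Tc, tau)

    # elongation: blend up (beta), plateau m_e, blend down (tau); unit area
    ue = _trapezoid_speed(np.linspace(0.0, Te, 513), Te, beta, tau)
    # contraction speed: mirror of the elongation turnaround (slope
    # m_e / tau) up to m_e at tau, blend to M over beta2, plateau, blend out
    def contr_speed(t, M, m_e):
        v = np.where(t < tau, m_e * t / tau, 0.0)
        v = np.where(
            (t >= tau) & (t < tau + beta2),
            m_e + (M - m_e) * (t - tau) / beta2,
            v,
        )
        v = np.where((t >= tau + beta2) & (t <= Tc - beta), M, v)
        v = np.where(t > Tc - beta, M * (Tc - t) / beta, v)
        return np.clip(v, 0.0, None)

    s = np.zeros_like(u)
    a = spec.iso_pre_frac
    b = a + spec.elong_frac
    c = b + spec.contr_frac

    rising = (u >= a) & (u < b)
    # cumulative elongation profile via interpolation of the speed integral
    grid_e = np.linspace(0.0, Te, 513)
    cum_e = np.concatenate([[0.0], np.cumsum((ue[1:] + ue[:-1]) / 2 * np.diff(grid_e))])
    cum_e /= cum_e[-1]
    s[rising] = np.interp((u[rising] - a) * T, grid_e, cum_e)

    m_e = 1.0 / np.trapezoid(ue, grid_e)  # elongation plateau speed, unit area
    # solve the contraction plateau M for unit area
    grid_c = np.linspace(0.0, Tc, 513)
    base = contr_speed(grid_c, 0.0, m_e)  # the mirrored turnaround part
    lin = contr_speed(grid_c, 1.0, m_e) - base  # area linear in M
    area_base = np.trapezoid(base, grid_c)
    area_lin = np.trapezoid(lin, grid_c)
    M = (1.0 - area_base) / area_lin if area_lin > 0 else m_e
    vc = contr_speed(grid_c, M, m_e)
    cum_c = np.concatenate([[0.0], np.cumsum((vc[1:] + vc[:-1]) / 2 * np.diff(grid_c))])
    cum_c /= cum_c[-1]
    falling = (u >= b) & (u < c)
    s[falling] = 1.0 - np.interp((u[falling] - b) * T, grid_c, cum_c)
    return s


def gen_behavior(spec: KinematicSpec, seed: int = 0) -> BehaviorRecording:
    """Generate a crawling bout of ``n_steps`` steps at ``fps``.

    All eight sections follow the same length profile (no intersegmental
    lag).  Point 1 is anterior, point 9 posterior; the rear endpoint is
    anchored during elongation and the front during contraction.  Additive
    Gaussian tracking noise of sd ``noise_sd`` per coordinate.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    T = spec.step_duration
    n = int(round(spec.n_steps * T * spec.fps)) + 1
    t = np.arange(n) / spec.fps
    step_idx = np.minimum((t / T).astype(int), spec.n_steps - 1)
    u = t / T - step_idx

    s = _step_profile(u, spec)
    sec_len = spec.section_rest_length * (1.0 + spec.elongation_gain * s)
    total = N_SECTIONS * sec_len

    # rear anchored while lengthening, front anchored while shortening
    dL = np.diff(total, prepend=total[0])
    x_post = np.cumsum(np.maximum(-dL, 0.0))
    # smooth whole-body creep, zero speed exactly at step boundaries
    creep_v = spec.creep_speed * np.sin(np.pi * u) ** 2
    x_post = x_post + np.cumsum(creep_v) / spec.fps
    x_ant = x_post + total

    points = np.zeros((n, N_POINTS, 2))
    for j in range(N_POINTS):
        points[:, j, 0] = x_post + (N_POINTS - 1 - j) * sec_len
    if spec.noise_sd > 0:
        points = points + rng.normal(0.0, spec.noise_sd, size=points.shape)

    steps = []
    for k in range(spec.n_steps):
        t0 = k * T
        elong_on = t0 + spec.iso_pre_frac * T
        max_t = elong_on + spec.elong_frac * T
        contr_end = max_t + spec.contr_frac * T
        steps.append(
            {
                "t_start": t0,
                "t_end": t0 + T,
                "elong_onset": elong_on,
                "max_length_time": max_t,
                "contr_end": contr_end,
            }
        )
    truth = GroundTruth(steps=steps)
    truth.validate()

    sections = np.repeat(sec_len[:, None], N_SECTIONS, axis=1)
    return BehaviorRecording(
        fps=spec.fps,
        points=points,
        likelihood=np.ones((n, N_POINTS)),
        section_lengths=sections,
        total_length=total,
        truth=truth,
        spec=spec,
    )
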