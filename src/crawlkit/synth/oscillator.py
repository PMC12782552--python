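"""Master oscillator: jittered crawling cycles with contraction windows."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ground_truth import GroundTruth
from .specs import OscillatorSpec

__all__ = ["Cycles", "gen_cycles"]


@dataclass
class Cycles:
    """Contiguous cycle intervals of the master oscillator.

    ``bounds[i] = [start_i, end_i)`` with ``start_{i+1} == end_i``;
    ``contraction[i]`` is the DE-3/contraction window opening cycle ``i``.
    """

    bounds: np.ndarray  # (n, 2)
    contraction: np.ndarray  # (n, 2)

    @property
    def n(self) -> int:
        return self.bounds.shape[0]

    @property
    def starts(self) -> np.ndarray:
        return self.bounds[:, 0]

    @property
    def ends(self) -> np.ndarray:
        return self.bounds[:, 1]

    @property
    def periods(self) -> np.ndarray:
        return self.bounds[:, 1] - self.bounds[:, 0]

    @property
    def span(self) -> tuple[float, float]:
        return float(self.bounds[0, 0]), float(self.bounds[-1, 1])

    def phase_of(self, t: np.ndarray) -> np.ndarray:
        """Map times to normalized phase in [0, 1) of their containing cycle.

        Times outside every cycle map to NaN.
        """
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.starts, t, side="right") - 1
        phase = np.full(t.shape, np.nan)
        ok = (idx >= 0) & (t < self.bounds[np.clip(idx, 0, self.n - 1), 1])
        i = idx[ok]
        phase[ok] = (t[ok] - self.bounds[i, 0]) / (
            self.bounds[i, 1] - self.bounds[i, 0]
        )
        return phase


def gen_cycles(spec: OscillatorSpec) -> tuple[Cycles, GroundTruth]:
    """Draw jittered cycle intervals from the oscillator spec.

    Per-cycle periods are Gaussian around ``period_mean`` with coefficient of
    variation ``period_cv`` (truncated below at 20% of the mean so a large
    jitter draw can never produce a degenerate cycle).  Each cycle opens with
    a contraction window of length ``contraction_duty`` x period.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    periods = spec.period_mean * (
        1.0 + spec.period_cv * rng.standard_normal(spec.n_cycles)
    )
    periods = np.maximum(periods, 0.2 * spec.period_mean)
    ends = np.cumsum(periods)
    starts = ends - periods
    bounds = np.column_stack([starts, ends])
    contraction = np.column_stack(
        [starts, starts + spec.contraction_duty * periods]
    )
    cycles = Cycles(bounds=bounds, contraction=contraction)
    truth = GroundTruth(cycles=bounds.copy(), contraction_windows=contraction.copy())
    truth.validate()
    return cycles, truth
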