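"""Uniformly sampled signal container shared by every stage of the toolkit.

A :class:`TimeSeries` wraps a 1-D array of samples with its sampling rate,
physical units and start time.  Extracellular nerve voltage, intracellular
membrane potential and body-section length traces all travel through the
pipeline in this form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TimeSeries"]


@dataclass
class TimeSeries:
    """A uniformly sampled scalar signal.

    Parameters
    ----------
    values :
        Sample values, one per time point.
    rate :
        Sampling rate in Hz; must be positive.
    units :
        Physical units of ``values`` (e.g. ``"uV"``, ``"mV"``, ``"mm"``).
    t0 :
        Time of the first sample in seconds.
    """

    values: np.ndarray
    rate: float
    units: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be 1-D")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        """Span covered by the samples, in seconds."""
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (clipped to range)."""
        i = int(round((t - self.t0) * self.rate))
        return min(max(i, 0), self.n - 1)

    def slice(self, t_start: float, t_stop: float) -> "TimeSeries":
        """Samples with times in ``[t_start, t_stop)`` as a new series."""
        i0 = max(int(np.ceil((t_start - self.t0) * self.rate)), 0)
        i1 = min(int(np.ceil((t_stop - self.t0) * self.rate)), self.n)
        return replace(
            self, values=self.values[i0:i1].copy(), t0=self.t0 + i0 / self.rate
        )

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        """Same grid and metadata, new samples (must match length)."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("replacement values must preserve shape")
        return replace(self, values=values)
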