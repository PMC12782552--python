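"""Readers and writers for the toolkit's on-disk formats.

Traces live in HDF5 containers (``/traces/<name>`` with ``rate``/``units``
attributes, ``/events/<unit>`` spike-time arrays); tabular outputs are CSV;
curation logs are JSON lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .timeseries import TimeSeries

__all__ = [
    "write_h5",
    "read_trace",
    "read_events",
    "write_spikes_csv",
    "read_spikes_csv",
    "write_templates_csv",
    "read_templates_csv",
    "write_curation_log",
    "read_curation_log",
    "read_trace_csv",
]


def write_h5(
    path,
    traces: dict[str, TimeSeries] | None = None,
    events: dict[str, np.ndarray] | None = None,
) -> None:
    """Write traces and/or spike-event arrays into one HDF5 container."""
    with h5py.File(path, "w") as f:
        for name, ts in (traces or {}).items():
            d = f.create_dataset(f"traces/{name}", data=ts.values)
            d.attrs["rate"] = ts.rate
            d.attrs["units"] = ts.units
            d.attrs["t0"] = ts.t0
        for unit, times in (events or {}).items():
            f.create_dataset(f"events/{unit}", data=np.asarray(times, dtype=float))


def read_trace(path, name: str) -> TimeSeries:
    with h5py.File(path, "r") as f:
        d = f[f"traces/{name}"]
        return TimeSeries(
            d[()],
            rate=float(d.attrs["rate"]),
            units=str(d.attrs.get("units", "")),
            t0=float(d.attrs.get("t0", 0.0)),
        )


def read_events(path) -> dict[str, np.ndarray]:
    out = {}
    with h5py.File(path, "r") as f:
        if "events" in f:
            for unit in f["events"]:
                out[unit] = f[f"events/{unit}"][()]
    return out


def read_trace_csv(path, rate: float | None = None) -> TimeSeries:
    """Read a (time, value) CSV trace; the rate is inferred when omitted."""
    df = pd.read_csv(path)
    t, v = df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy()
    if rate is None:
        dt = np.median(np.diff(t))
        if dt <= 0:
            raise ValueError("non-increasing time column")
        rate = 1.0 / dt
    return TimeSeries(v, rate=rate, t0=float(t[0]))


def write_spikes_csv(path, spikes: dict[str, np.ndarray], channel: str = "DP") -> None:
    """Per-unit spike-time table: unit_id, channel, time_s."""
    rows = []
    for uid, times in spikes.items():
        for t in np.asarray(times, dtype=float):
            rows.append({"unit_id": uid, "channel": channel, "time_s": t})
    pd.DataFrame(rows, columns=["unit_id", "channel", "time_s"]).to_csv(
        path, index=False
    )


def read_spikes_csv(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {
        str(uid): np.sort(grp["time_s"].to_numpy())
        for uid, grp in df.groupby("unit_id")
    }


def write_templates_csv(path, templates: dict[str, np.ndarray]) -> None:
    """Template matrix, one row per unit (first column = unit id)."""
    df = pd.DataFrame(
        {uid: np.asarray(t, dtype=float) for uid, t in templates.items()}
    ).T
    df.index.name = "unit_id"
    df.to_csv(path)


def read_templates_csv(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    return {str(uid): row.to_numpy() for uid, row in df.iterrows()}


def write_curation_log(path, log: list[dict]) -> None:
    Path(path).write_text("".join(json.dumps(e) + "\n" for e in log))


def read_curation_log(path) -> list[dict]:
    lines = Path(path).read_text().splitlines()
    return [json.loads(ln) for ln in lines if ln.strip()]
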