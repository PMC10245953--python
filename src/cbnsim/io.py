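"""Plain-text interchange formats.

Spike trains travel as two-column CSV (``unit_id,time_s``, 6 decimal
places), conductance waveforms as ``time_ms,conductance_nS`` (the exchange
format a dynamic-clamp rig consumes), and weight lists as one-column CSV
in nS.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conductance import ConductanceTrace
from .spike_gen import SpikeTrain

__all__ = [
    "write_spike_csv",
    "read_spike_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_weights_csv",
    "read_weights_csv",
]


def write_spike_csv(trains: Mapping[str, SpikeTrain] | SpikeTrain,
                    path: str | Path) -> None:
    """Write one or more spike trains as ``unit_id,time_s`` rows."""
    if isinstance(trains, SpikeTrain):
        trains = {trains.unit_id or "unit0": trains}
    frames = [
        pd.DataFrame({"unit_id": label, "time_s": t.times})
        for label, t in trains.items()
    ]
    df = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=["unit_id", "time_s"])
    df.to_csv(path, index=False, float_format="%.6f")


def read_spike_csv(path: str | Path,
                   duration: float | None = None) -> dict[str, SpikeTrain]:
    """Read spike trains; times per unit must already be sorted.

    ``duration`` defaults to the last spike time plus one microsecond.
    Raises ``ValueError`` naming the offending line for malformed or
    unsorted input.
    """
    df = pd.read_csv(path)
    expected = ["unit_id", "time_s"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: header must be {','.join(expected)}")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    bad = times.index[times.isna()]
    if bad.size:
        raise ValueError(f"{path}: non-numeric time_s on line {bad[0] + 2}")
    out: dict[str, SpikeTrain] = {}
    full = duration if duration is not None else \
        (float(times.max()) + 1e-6 if len(df) else 0.0)
    for label, grp in df.groupby("unit_id", sort=False):
        t = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            row = int(grp.index[np.flatnonzero(np.diff(t) <= 0)[0] + 1])
            raise ValueError(
                f"{path}: spike times for unit {label!r} not strictly "
                f"increasing at line {row + 2}")
        out[str(label)] = SpikeTrain(t, full, str(label))
    return out


def write_trace_csv(trace: ConductanceTrace, path: str | Path,
                    decimate: int = 1) -> None:
    """Export a conductance waveform as ``time_ms,conductance_nS``."""
    pd.DataFrame({
        "time_ms": trace.times_ms[::decimate],
        "conductance_nS": trace.values[::decimate],
    }).to_csv(path, index=False, float_format="%.6f")


def read_trace_csv(path: str | Path) -> ConductanceTrace:
    df = pd.read_csv(path)
    expected = ["time_ms", "conductance_nS"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: header must be {','.join(expected)}")
    t = df["time_ms"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    dts = np.diff(t)
    dt = float(dts[0])
    if dt <= 0 or not np.allclose(dts, dt, rtol=0, atol=1e-6):
        raise ValueError(f"{path}: time grid must be uniform and increasing")
    return ConductanceTrace(dt, df["conductance_nS"].to_numpy(dtype=float),
                            t0=float(t[0]))


def write_weights_csv(weights: Sequence[float], path: str | Path) -> None:
    pd.DataFrame({"weight_nS": np.asarray(weights, dtype=float)}).to_csv(
        path, index=False, float_format="%.6f")


def read_weights_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    if list(df.columns) != ["weight_nS"]:
        raise ValueError(f"{path}: header must be weight_nS")
    w = df["weight_nS"].to_numpy(dtype=float)
    if np.any(~np.isfinite(w)) or np.any(w < 0):
        raise ValueError(f"{path}: weights must be finite and >= 0")
    return w
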