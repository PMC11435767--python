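"""Core domain types and CSV/JSON readers and writers.

All acceleration is held internally in m/s^2 (SI); CSV readers convert
g-unit exports on ingest.  Sample indices are 0-based and the time of
sample ``k`` is ``t0 + k / fs``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from strokewave.errors import DataError

log = logging.getLogger(__name__)

#: Standard gravity used for g -> m/s^2 conversion.
STANDARD_GRAVITY = 9.80665

#: Nominal accelerometer rate the detection cascade was designed around (Hz).
NOMINAL_ACCEL_FS = 200.0

#: Maximum relative timestamp jitter tolerated when inferring the sample rate.
MAX_TIMESTAMP_JITTER = 0.01


@dataclass(frozen=True)
class SensorSpec:
    """Static accelerometer parameters.

    Parameters
    ----------
    sample_rate_hz : float
        Nominal sampling rate in Hz.
    range_g : float
        Full-scale measurement range in g.
    axis_convention : str
        Label of the forward (boat-travel) axis.
    """

    sample_rate_hz: float = 200.0
    range_g: float = 16.0
    axis_convention: str = "x-forward"

    def __post_init__(self) -> None:
        if not self.sample_rate_hz > 0:
            raise DataError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if not self.range_g > 0:
            raise DataError(f"range_g must be > 0, got {self.range_g}")


@dataclass
class AccelTrace:
    """Uniformly sampled tri-axial hull acceleration (m/s^2)."""

    t0: float
    fs: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    spec: SensorSpec = field(default_factory=SensorSpec)

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise DataError("axes must have equal length")
        if len(self.ax) < 1:
            raise DataError("trace must contain at least one sample")
        for name, arr in (("ax", self.ax), ("ay", self.ay), ("az", self.az)):
            if not np.all(np.isfinite(arr)):
                raise DataError(f"non-finite values in {name}")
        if not math.isclose(self.fs, self.spec.sample_rate_hz, rel_tol=1e-9):
            raise DataError(
                f"fs ({self.fs}) does not match spec.sample_rate_hz "
                f"({self.spec.sample_rate_hz})"
            )
        if not math.isclose(self.fs, NOMINAL_ACCEL_FS, rel_tol=1e-9):
            # The detection cascade was tuned for 200 Hz; other rates may need
            # different decomposition levels.
            log.warning(
                "accelerometer rate %.6g Hz differs from the nominal %.6g Hz; "
                "approximation-level choices may need revisiting",
                self.fs,
                NOMINAL_ACCEL_FS,
            )

    def __len__(self) -> int:
        return len(self.ax)

    @property
    def duration_s(self) -> float:
        return len(self.ax) / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.ax)) / self.fs


@dataclass
class ForceTrace:
    """Multi-gate horizontal oarlock force (N), uniformly sampled."""

    t0: float
    fs: float
    gates: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise DataError(f"fs must be > 0, got {self.fs}")
        if len(self.gates) < 1:
            raise DataError("at least one gate is required")
        self.gates = [np.asarray(g, dtype=float) for g in self.gates]
        n = len(self.gates[0])
        if any(len(g) != n for g in self.gates):
            raise DataError("all gate sequences must have equal length")

    @property
    def n_gates(self) -> int:
        return len(self.gates)

    def __len__(self) -> int:
        return len(self.gates[0])

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs


@dataclass(frozen=True)
class StrokeEvent:
    """Per-stroke event triple, as 0-based sample indices."""

    cycle_start: int
    drive_start: int
    drive_end: int

    def __post_init__(self) -> None:
        if not (self.cycle_start <= self.drive_start < self.drive_end):
            raise DataError(
                f"event ordering violated: C_S={self.cycle_start}, "
                f"D_S={self.drive_start}, D_E={self.drive_end}"
            )


@dataclass
class StrokeEventSet:
    """Ordered, non-overlapping stroke events with their sampling rate."""

    events: list[StrokeEvent]
    fs: float

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise DataError(f"fs must be > 0, got {self.fs}")
        for prev, cur in zip(self.events, self.events[1:]):
            if not prev.drive_end < cur.cycle_start:
                raise DataError(
                    f"strokes overlap: D_E={prev.drive_end} not before "
                    f"next C_S={cur.cycle_start}"
                )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def cycle_starts(self) -> np.ndarray:
        return np.array([e.cycle_start for e in self.events], dtype=int)

    def drive_starts(self) -> np.ndarray:
        return np.array([e.drive_start for e in self.events], dtype=int)

    def drive_ends(self) -> np.ndarray:
        return np.array([e.drive_end for e in self.events], dtype=int)


@dataclass
class StrokeMetrics:
    """Per-stroke drive time and inter-stroke stroke time, in seconds."""

    drive_time: np.ndarray
    stroke_time: np.ndarray

    def __post_init__(self) -> None:
        self.drive_time = np.asarray(self.drive_time, dtype=float)
        self.stroke_time = np.asarray(self.stroke_time, dtype=float)
        if np.any(self.drive_time <= 0):
            raise DataError("drive times must be positive")
        if np.any(self.stroke_time <= 0):
            raise DataError("stroke times must be positive")


# ---------------------------------------------------------------------------
# CSV / JSON I/O
# ---------------------------------------------------------------------------

_DEFAULT_IMU_COLUMNS: Mapping[str, str] = {
    "time": "time",
    "ax": "ax",
    "ay": "ay",
    "az": "az",
}


def _infer_fs(t: np.ndarray) -> float:
    """Infer the sampling rate from a timestamp column.

    Raises :class:`DataError` if the timestamps are not uniformly increasing
    to within :data:`MAX_TIMESTAMP_JITTER` relative jitter.
    """
    if len(t) < 2:
        raise DataError("need at least two timestamps to infer the sample rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DataError("timestamps are not strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > MAX_TIMESTAMP_JITTER * med:
        raise DataError(
            "non-uniform sampling: timestamp jitter exceeds "
            f"{MAX_TIMESTAMP_JITTER:.0%} of the median interval"
        )
    fs = 1.0 / med
    # snap float-quantization residue (e.g. 49.99999999999996 -> 50)
    if abs(fs - round(fs)) < 1e-6 * fs:
        fs = float(round(fs))
    return fs


def read_imu_csv(
    path: str | Path,
    spec: SensorSpec | None = None,
    column_map: Mapping[str, str] | None = None,
    units: str = "m/s2",
) -> AccelTrace:
    """Read an IMU CSV export into an :class:`AccelTrace`.

    Parameters
    ----------
    path : path-like
        CSV with a header row, a time column (seconds) and three
        acceleration columns.
    spec : SensorSpec, optional
        Declared sensor parameters; the inferred rate must match
        ``spec.sample_rate_hz`` within 1%.
    column_map : mapping, optional
        Maps the logical names ``time, ax, ay, az`` to CSV column names.
    units : {"m/s2", "g"}
        Units of the acceleration columns; ``g`` values are converted to
        m/s^2 with standard gravity.
    """
    spec = spec or SensorSpec()
    cols = dict(_DEFAULT_IMU_COLUMNS)
    if column_map:
        cols.update(column_map)
    if units not in ("m/s2", "g"):
        raise DataError(f"units must be 'm/s2' or 'g', got {units!r}")
    df = pd.read_csv(path)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise DataError(f"missing columns in {path}: {missing}")
    t = df[cols["time"]].to_numpy(dtype=float)
    fs = _infer_fs(t)
    if abs(fs - spec.sample_rate_hz) > 0.01 * spec.sample_rate_hz:
        raise DataError(
            f"inferred rate {fs:.4g} Hz does not match declared "
            f"{spec.sample_rate_hz:.4g} Hz within 1%"
        )
    scale = STANDARD_GRAVITY if units == "g" else 1.0
    return AccelTrace(
        t0=float(t[0]),
        fs=spec.sample_rate_hz,
        ax=df[cols["ax"]].to_numpy(dtype=float) * scale,
        ay=df[cols["ay"]].to_numpy(dtype=float) * scale,
        az=df[cols["az"]].to_numpy(dtype=float) * scale,
        spec=spec,
    )


def write_imu_csv(trace: AccelTrace, path: str | Path) -> None:
    """Write an :class:`AccelTrace` as a CSV (time in s, axes in m/s^2)."""
    pd.DataFrame(
        {"time": trace.times(), "ax": trace.ax, "ay": trace.ay, "az": trace.az}
    ).to_csv(path, index=False)


def read_force_csv(
    path: str | Path,
    gate_columns: Sequence[str] | None = None,
    fs: float = 50.0,
    time_column: str = "time",
) -> ForceTrace:
    """Read a per-gate horizontal force CSV into a :class:`ForceTrace`.

    ``gate_columns`` selects (and orders) the gate columns; by default every
    column other than the time column is treated as a gate, in file order.
    If a time column is present the rate is inferred from it, otherwise
    ``fs`` is used and ``t0`` is 0.
    """
    df = pd.read_csv(path)
    t0 = 0.0
    if time_column in df.columns:
        t = df[time_column].to_numpy(dtype=float)
        fs = _infer_fs(t)
        t0 = float(t[0])
        df = df.drop(columns=[time_column])
    if gate_columns is None:
        gate_columns = list(df.columns)
    if len(gate_columns) == 0:
        raise DataError("empty gate column list")
    missing = [c for c in gate_columns if c not in df.columns]
    if missing:
        raise DataError(f"missing gate columns in {path}: {missing}")
    gates = [df[c].to_numpy(dtype=float) for c in gate_columns]
    return ForceTrace(t0=t0, fs=fs, gates=gates)


def write_force_csv(trace: ForceTrace, path: str | Path) -> None:
    """Write a :class:`ForceTrace` as CSV with a time column and one column
    per gate (``gate1``, ``gate2``, ...)."""
    data: dict[str, np.ndarray] = {"time": trace.times()}
    for i, g in enumerate(trace.gates, start=1):
        data[f"gate{i}"] = g
    pd.DataFrame(data).to_csv(path, index=False)


_EVENT_COLUMNS = [
    "stroke",
    "cycle_start",
    "drive_start",
    "drive_end",
    "cycle_start_s",
    "drive_start_s",
    "drive_end_s",
]


def write_events_csv(events: StrokeEventSet, path: str | Path, t0: float = 0.0) -> None:
    """Write stroke events as CSV, one row per stroke.

    Indices are written both as raw samples and as seconds
    (``t0 + index / fs``). An empty event set yields a header-only file.
    """
    rows = [
        {
            "stroke": i,
            "cycle_start": e.cycle_start,
            "drive_start": e.drive_start,
            "drive_end": e.drive_end,
            "cycle_start_s": t0 + e.cycle_start / events.fs,
            "drive_start_s": t0 + e.drive_start / events.fs,
            "drive_end_s": t0 + e.drive_end / events.fs,
        }
        for i, e in enumerate(events.events)
    ]
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False)


def read_events_csv(path: str | Path, fs: float) -> StrokeEventSet:
    """Read a stroke-event CSV written by :func:`write_events_csv`."""
    df = pd.read_csv(path)
    missing = [c for c in ("cycle_start", "drive_start", "drive_end") if c not in df.columns]
    if missing:
        raise DataError(f"missing columns in {path}: {missing}")
    events = [
        StrokeEvent(int(r.cycle_start), int(r.drive_start), int(r.drive_end))
        for r in df.itertuples()
    ]
    return StrokeEventSet(events=events, fs=fs)


def write_report_json(report: dict, path: str | Path) -> None:
    """Serialize a (JSON-compatible) report dict, converting numpy scalars."""

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_report_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
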