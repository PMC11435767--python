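"""Oarlock-force reference features.

Summed gate force -> per-stroke peak -> first positive-to-negative zero
crossing after the peak (sub-sample interpolated) as the force drive end;
consecutive drive-end differences give the force stroke time.  A
configurable threshold-crossing surrogate stands in for the proprietary
per-gate drive-time algorithm, averaged across gates per stroke.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from strokewave.errors import DataError
from strokewave.signal_model import ForceTrace
from strokewave.stroke_detection import PeakConfig, robust_amplitude

log = logging.getLogger(__name__)

#: Default surrogate rise/fall threshold per gate (N). Non-canonical: the
#: real system's thresholds are proprietary; chosen well above the
#: generator noise floor but low enough that the clipped pulse shoulders
#: stay small against a full-size drive pulse.
DEFAULT_THRESHOLD_N = 10.0


@dataclass
class ForceEvents:
    """Per-stroke force features.

    ``peaks``: indices of summed-force maxima.  ``drive_end_times``: the
    interpolated positive-to-negative crossing times (s) after each peak
    (NaN where no crossing exists).  ``drive_times``: the threshold
    surrogate drive time averaged across gates (NaN where missing).
    """

    peaks: np.ndarray
    drive_end_times: np.ndarray
    fs: float
    drive_times: np.ndarray | None = None
    per_gate_drive_times: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=int)
        self.drive_end_times = np.asarray(self.drive_end_times, dtype=float)
        if len(self.peaks) != len(self.drive_end_times):
            raise DataError("peaks and drive_end_times must have equal length")
        ok = np.isfinite(self.drive_end_times)
        if np.any(np.diff(self.drive_end_times[ok]) <= 0):
            raise DataError("drive-end times must be strictly increasing")

    def valid_drive_ends(self) -> np.ndarray:
        return self.drive_end_times[np.isfinite(self.drive_end_times)]


def sum_gate_forces(f: ForceTrace) -> np.ndarray:
    """Elementwise sum across gates: total horizontal system force."""
    return np.sum(np.vstack(f.gates), axis=0)


def detect_force_peaks(
    f_total: np.ndarray, fs: float, cfg: PeakConfig | None = None
) -> np.ndarray:
    """One dominant summed-force peak per stroke (sorted indices)."""
    cfg = cfg or PeakConfig()
    if not fs > 0:
        raise DataError("fs must be > 0")
    f_total = np.asarray(f_total, dtype=float)
    amp = robust_amplitude(f_total)
    if amp == 0.0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(
        f_total,
        distance=max(1, int(round(cfg.min_separation_s * fs))),
        prominence=cfg.min_prominence_frac * amp,
    )
    return peaks.astype(int)


def detect_force_drive_end(
    f_total: np.ndarray, peak_idx: int, fs: float, t0: float = 0.0
) -> float:
    """First positive-to-negative zero crossing after ``peak_idx``.

    Returns the crossing time in seconds, linearly interpolated between the
    bracketing samples; NaN (logged) if the trace never crosses before its
    end.
    """
    f_total = np.asarray(f_total, dtype=float)
    if not f_total[peak_idx] > 0:
        raise DataError(f"force at peak index {peak_idx} is not positive")
    seg = f_total[peak_idx:]
    neg = np.nonzero((seg[:-1] >= 0) & (seg[1:] < 0))[0]
    if len(neg) == 0:
        log.warning("no positive-to-negative crossing after peak %d", peak_idx)
        return float("nan")
    k = peak_idx + int(neg[0])
    frac = f_total[k] / (f_total[k] - f_total[k + 1])
    return t0 + (k + frac) / fs


def force_stroke_times(drive_end_times: np.ndarray) -> np.ndarray:
    """Consecutive drive-end differences ``ST_F(n) = D_EF(n) - D_EF(n-1)``."""
    t = np.asarray(drive_end_times, dtype=float)
    t = t[np.isfinite(t)]
    st = np.diff(t)
    if np.any(st <= 0):
        raise DataError("drive-end times must be strictly increasing")
    return st


def _threshold_crossing_times(
    force: np.ndarray, peak: int, fs: float, rise_threshold: float, fall_threshold: float
) -> tuple[float, float] | None:
    """Interpolated rise/fall threshold crossings bracketing ``peak``."""
    if force[peak] < max(rise_threshold, fall_threshold):
        return None
    below = np.nonzero(force[:peak] < rise_threshold)[0]
    if len(below) == 0:
        return None
    k = int(below[-1])  # last sample below threshold before the peak
    frac = (rise_threshold - force[k]) / (force[k + 1] - force[k])
    t_rise = (k + frac) / fs
    after = np.nonzero(force[peak:] < fall_threshold)[0]
    if len(after) == 0:
        return None
    k = peak + int(after[0]) - 1  # last sample at/above threshold
    frac = (force[k] - fall_threshold) / (force[k] - force[k + 1])
    t_fall = (k + frac) / fs
    return t_rise, t_fall


def threshold_drive_time(
    gate_force: np.ndarray,
    fs: float,
    rise_threshold_n: float = DEFAULT_THRESHOLD_N,
    fall_threshold_n: float = DEFAULT_THRESHOLD_N,
    cfg: PeakConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-stroke threshold-crossing drive times for one gate.

    For each detected force pulse the drive time is the interval between
    the rising crossing of ``rise_threshold_n`` and the falling crossing of
    ``fall_threshold_n`` (both sub-sample interpolated).  Returns
    ``(peak_times_s, drive_times_s)`` with NaN where a threshold is never
    crossed.
    """
    if rise_threshold_n <= 0 or fall_threshold_n <= 0:
        raise DataError("thresholds must be > 0")
    gate_force = np.asarray(gate_force, dtype=float)
    peaks = detect_force_peaks(gate_force, fs, cfg)
    times = peaks / fs
    dts = np.full(len(peaks), np.nan)
    for i, p in enumerate(peaks):
        crossing = _threshold_crossing_times(gate_force, int(p), fs, rise_threshold_n, fall_threshold_n)
        if crossing is None:
            log.warning("threshold never crossed for pulse at index %d", p)
            continue
        dts[i] = crossing[1] - crossing[0]
    return times, dts


def average_gate_drive_times(
    trace: ForceTrace,
    rise_threshold_n: float = DEFAULT_THRESHOLD_N,
    fall_threshold_n: float = DEFAULT_THRESHOLD_N,
    cfg: PeakConfig | None = None,
    match_tol_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold drive times averaged across gates, per stroke.

    Strokes are anchored on the first gate's pulses; each other gate
    contributes its nearest pulse within ``match_tol_s`` (default: half the
    median inter-pulse interval).  Returns ``(anchor_peak_times_s,
    mean_drive_times_s)``.
    """
    per_gate = [
        threshold_drive_time(g, trace.fs, rise_threshold_n, fall_threshold_n, cfg)
        for g in trace.gates
    ]
    anchor_times, anchor_dts = per_gate[0]
    if len(anchor_times) == 0:
        return anchor_times, anchor_dts
    if match_tol_s is None:
        med = np.median(np.diff(anchor_times)) if len(anchor_times) > 1 else np.inf
        match_tol_s = 0.5 * float(med)
    out = np.full(len(anchor_times), np.nan)
    for i, t in enumerate(anchor_times):
        vals = []
        for times, dts in per_gate:
            if len(times) == 0:
                continue
            j = int(np.argmin(np.abs(times - t)))
            if abs(times[j] - t) <= match_tol_s and np.isfinite(dts[j]):
                vals.append(dts[j])
        if vals:
            out[i] = float(np.mean(vals))
    return anchor_times + trace.t0, out


def force_events(
    trace: ForceTrace,
    cfg: PeakConfig | None = None,
    rise_threshold_n: float = DEFAULT_THRESHOLD_N,
    fall_threshold_n: float = DEFAULT_THRESHOLD_N,
) -> ForceEvents:
    """Full force-side pipeline: sum gates, find per-stroke peaks, locate
    drive ends, and compute the surrogate (gate-averaged) drive times."""
    f_total = sum_gate_forces(trace)
    peaks = detect_force_peaks(f_total, trace.fs, cfg)
    d_ef = np.array(
        [detect_force_drive_end(f_total, int(p), trace.fs, trace.t0) for p in peaks]
    )
    anchor_times, mean_dts = average_gate_drive_times(
        trace, rise_threshold_n, fall_threshold_n, cfg
    )
    # align surrogate drive times to the summed-force peaks
    dts = np.full(len(peaks), np.nan)
    peak_times = peaks / trace.fs + trace.t0
    if len(anchor_times):
        tol = 0.5 * float(np.median(np.diff(peak_times))) if len(peaks) > 1 else np.inf
        for i, t in enumerate(peak_times):
            j = int(np.argmin(np.abs(anchor_times - t)))
            if abs(anchor_times[j] - t) <= tol:
                dts[i] = mean_dts[j]
    return ForceEvents(
        peaks=peaks, drive_end_times=d_ef, fs=trace.fs, drive_times=dts
    )


def pair_events(
    accel_times: np.ndarray, force_times: np.ndarray, tol_s: float | None = None
) -> tuple[list[tuple[int, int]], int]:
    """Match accelerometer events to force events by nearest time.

    Each accelerometer time is matched to the nearest force time within
    ``tol_s`` (default: half the median accelerometer inter-event
    interval); a force event is used at most once.  Returns the matched
    index pairs and the number of unmatched accelerometer events.
    """
    a = np.asarray(accel_times, dtype=float)
    f = np.asarray(force_times, dtype=float)
    if tol_s is None:
        tol_s = 0.5 * float(np.median(np.diff(a))) if len(a) > 1 else np.inf
    pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    for i, t in enumerate(a):
        if len(f) == 0:
            break
        j = int(np.argmin(np.abs(f - t)))
        if abs(f[j] - t) <= tol_s and j not in used:
            pairs.append((i, j))
            used.add(j)
    dropped = len(a) - len(pairs)
    if dropped:
        log.info("pairing dropped %d unmatched accelerometer event(s)", dropped)
    return pairs, dropped
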