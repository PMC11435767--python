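"""Stroke feature detection from the wavelet-decomposed acceleration.

The cascade: negate the level-3 approximation and peak-search it for drive
starts (catch troughs); segment the session between consecutive drive
starts; within each segment, the last local maximum of the level-3
approximation (the first peak of the time-reversed segment) is the cycle
start; within each cycle-start window, the first local minimum of the
level-2 approximation after its in-window maximum is the drive end.
Detection is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from strokewave.errors import DataError, NoStrokesError
from strokewave.signal_model import AccelTrace, StrokeEvent, StrokeEventSet, StrokeMetrics
from strokewave.uwt import approximation, uwt_decompose

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakConfig:
    """Peak-search parameters for the drive-start (and force-peak) detectors.

    ``min_separation_s`` is the smallest admissible inter-stroke interval;
    by default it corresponds to a 60 strokes-per-minute ceiling.
    ``min_prominence_frac`` scales the coefficient's robust amplitude
    (5th-95th percentile span), making detection invariant to positive
    rescaling of the signal.
    """

    min_separation_s: float = 1.0
    min_prominence_frac: float = 0.25
    #: Featureless-input gate: with >= 4 trough candidates, the normalized
    #: autocorrelation of the coefficient must exceed this somewhere in the
    #: stroke-period band, or no strokes are reported.  Rowing sessions are
    #: quasi-periodic (autocorrelation > 0.5 at the stroke lag) while
    #: variance-matched noise decorrelates within tens of milliseconds.
    #: 0 disables the gate.
    min_periodicity: float = 0.2

    def __post_init__(self) -> None:
        if not self.min_separation_s > 0:
            raise DataError("min_separation_s must be > 0")
        if not 0 < self.min_prominence_frac < 1:
            raise DataError("min_prominence_frac must be in (0, 1)")
        if not 0 <= self.min_periodicity < 1:
            raise DataError("min_periodicity must be in [0, 1)")

    @classmethod
    def from_max_stroke_rate(
        cls, max_stroke_rate_spm: float = 60.0, min_prominence_frac: float = 0.25
    ) -> "PeakConfig":
        return cls(
            min_separation_s=60.0 / max_stroke_rate_spm,
            min_prominence_frac=min_prominence_frac,
        )


def robust_amplitude(x: np.ndarray) -> float:
    """5th-95th percentile span; scale reference for prominence thresholds."""
    lo, hi = np.percentile(x, [5.0, 95.0])
    return float(hi - lo)


def detect_drive_starts(cA3: np.ndarray, fs: float, cfg: PeakConfig | None = None) -> np.ndarray:
    """Locate drive starts as prominent local maxima of the negated level-3
    approximation (i.e. the deep catch troughs). Returns sorted indices;
    a constant or featureless signal yields an empty array.
    """
    cfg = cfg or PeakConfig()
    cA3 = np.asarray(cA3, dtype=float)
    if not fs > 0:
        raise DataError("fs must be > 0")
    amp = robust_amplitude(cA3)
    if amp == 0.0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(
        -cA3,
        distance=max(1, int(round(cfg.min_separation_s * fs))),
        prominence=cfg.min_prominence_frac * amp,
    )
    if len(peaks) >= 4 and cfg.min_periodicity > 0:
        if _stroke_band_periodicity(cA3, fs, cfg.min_separation_s) < cfg.min_periodicity:
            log.warning("input is not quasi-periodic in the stroke band; no strokes")
            return np.array([], dtype=int)
    return peaks.astype(int)


def _stroke_band_periodicity(x: np.ndarray, fs: float, min_lag_s: float,
                             max_lag_s: float = 3.0) -> float:
    """Maximum of the biased normalized autocorrelation over stroke-period lags."""
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return 0.0
    n = len(x)
    lo = max(1, int(round(min_lag_s * fs)))
    hi = min(n - 1, int(round(max_lag_s * fs)))
    if lo > hi:
        return 0.0
    spec = np.fft.rfft(x, 2 * n)
    ac = np.fft.irfft(spec * np.conj(spec))[: n]
    return float(np.max(ac[lo : hi + 1]) / denom)


def segment_strokes(drive_starts: np.ndarray, n_samples: int) -> list[tuple[int, int]]:
    """Half-open ``[D_S(i), D_S(i+1))`` segments between consecutive drive
    starts. Fewer than two indices yields an empty list."""
    ds = np.asarray(drive_starts, dtype=int)
    if len(ds) >= 2 and np.any(np.diff(ds) <= 0):
        raise DataError("drive-start indices must be strictly increasing")
    if len(ds) and (ds[0] < 0 or ds[-1] >= n_samples):
        raise DataError("drive-start indices out of range")
    return [(int(a), int(b)) for a, b in zip(ds[:-1], ds[1:])]


def _local_maxima(seg: np.ndarray, prominence: float | None) -> np.ndarray:
    """Local-maximum indices; plateaus resolve to their earliest sample."""
    peaks, props = find_peaks(seg, plateau_size=(1, None), prominence=prominence)
    return props["left_edges"].astype(int)


def detect_cycle_start(cA3: np.ndarray, segment: tuple[int, int], cfg: PeakConfig | None = None) -> int:
    """Cycle start for the stroke whose trough *terminates* ``segment``.

    Equivalent to the first peak of the time-reversed segment: the last
    local maximum of the level-3 approximation before the next catch.
    Prefers maxima whose prominence clears ``min_prominence_frac`` of the
    segment's robust amplitude (rejecting noise wrinkles); falls back to
    the last plain local maximum, then to the final segment sample
    (logged) if the segment is monotone.
    """
    cfg = cfg or PeakConfig()
    start, end = segment
    if not 0 <= start < end <= len(cA3):
        raise DataError(f"invalid segment {segment} for trace of length {len(cA3)}")
    seg = np.asarray(cA3[start:end], dtype=float)
    prom = cfg.min_prominence_frac * robust_amplitude(seg)
    maxima = _local_maxima(seg, prom if prom > 0 else None)
    if len(maxima) == 0:
        maxima = _local_maxima(seg, None)
    if len(maxima) == 0:
        log.warning("no cycle-start peak in segment [%d, %d); using segment end", start, end)
        return end - 1
    return start + int(maxima[-1])


def detect_drive_end(cA2: np.ndarray, window: tuple[int, int], cfg: PeakConfig | None = None) -> int:
    """Drive end within a ``[C_S, next C_S)`` window.

    The in-window global maximum of the level-2 approximation is the drive
    peak; the drive end is the first local minimum after it (the
    post-drive valley).  Minima must clear ``min_prominence_frac`` of the
    window's robust amplitude; failing that, the first plain local
    minimum, then the first flattening of the descent (derivative turning
    non-negative), then the window midpoint (logged).
    """
    cfg = cfg or PeakConfig()
    start, end = window
    if not 0 <= start < end <= len(cA2):
        raise DataError(f"invalid window {window} for trace of length {len(cA2)}")
    seg = np.asarray(cA2[start:end], dtype=float)
    peak = int(np.argmax(seg))
    tail = -seg[peak:]
    prom = cfg.min_prominence_frac * robust_amplitude(seg)
    minima = _local_maxima(tail, prom if prom > 0 else None)
    if len(minima) == 0:
        minima = _local_maxima(tail, None)
    if len(minima) > 0:
        return start + peak + int(minima[0])
    # descent that flattens without turning: first non-negative derivative
    diff = np.diff(seg[peak:])
    falling = False
    for i, d in enumerate(diff):
        if d < 0:
            falling = True
        elif falling and d >= 0:
            return start + peak + i
    mid = start + (end - start) // 2
    log.warning(
        "no post-peak minimum in window [%d, %d); falling back to midpoint %d",
        start, end, mid,
    )
    return mid


def detect_stroke_events(
    trace: AccelTrace,
    cfg: PeakConfig | None = None,
    levels: int = 9,
    wavelet_name: str = "bior4.4",
) -> StrokeEventSet:
    """Run the full detection cascade on an acceleration trace.

    Decomposes the forward axis, finds drive starts on the negated level-3
    approximation, segments the session, then locates each stroke's cycle
    start and drive end.  The first and last partial strokes are discarded
    (each feature search needs a complete neighbouring trough).  Raises
    :class:`NoStrokesError` if fewer than two drive starts are found.
    """
    cfg = cfg or PeakConfig()
    decomp = uwt_decompose(trace.ax, levels=levels, wavelet_name=wavelet_name)
    cA3 = approximation(decomp, 3)
    cA2 = approximation(decomp, 2)

    ds = detect_drive_starts(cA3, trace.fs, cfg)
    if len(ds) < 2:
        raise NoStrokesError(f"only {len(ds)} drive start(s) detected; need >= 2")

    segments = segment_strokes(ds, len(trace))
    # cycle start of the stroke beginning at ds[i+1] comes from segment i
    cycle_starts = {
        i + 1: detect_cycle_start(cA3, seg, cfg) for i, seg in enumerate(segments)
    }

    events: list[StrokeEvent] = []
    for i in range(1, len(ds) - 1):
        cs, cs_next = cycle_starts[i], cycle_starts[i + 1]
        if cs_next <= cs:  # degenerate fallback ordering; skip stroke
            log.warning("skipping stroke %d: empty cycle window [%d, %d)", i, cs, cs_next)
            continue
        de = detect_drive_end(cA2, (cs, cs_next), cfg)
        if not (cs <= ds[i] < de):
            log.warning(
                "skipping stroke %d: inconsistent events C_S=%d D_S=%d D_E=%d",
                i, cs, ds[i], de,
            )
            continue
        if events and de <= events[-1].drive_end:
            log.warning("skipping stroke %d: non-increasing drive end", i)
            continue
        events.append(StrokeEvent(int(cs), int(ds[i]), int(de)))

    return StrokeEventSet(events=events, fs=trace.fs)


def compute_metrics(events: StrokeEventSet) -> StrokeMetrics:
    """Drive time per stroke and stroke time per consecutive stroke pair.

    ``DT(i) = (D_E(i) - D_S(i)) / fs``;
    ``ST(i) = (D_E(i+1) - D_E(i)) / fs``.
    """
    if len(events) < 1:
        raise DataError("empty event set")
    de = events.drive_ends()
    dt = (de - events.drive_starts()) / events.fs
    st = np.diff(de) / events.fs
    return StrokeMetrics(drive_time=dt, stroke_time=st)
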