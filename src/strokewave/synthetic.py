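"""Synthetic paired acceleration / oarlock-force sessions with ground truth.

Each stroke's forward hull acceleration is a sum of Gaussian bumps on a
zero baseline reproducing the stereotyped per-stroke topology: a recovery
hump (cycle start), a deep catch trough (drive start), a positive drive
peak, and a post-drive valley (drive end).  Ground-truth event indices are
the exact extrema of the noiseless composite, located numerically near
each nominal landmark, so they remain valid even where neighbouring bumps
interact.  The force channel places, per gate, a half-sine pulse spanning
each drive on a small negative baseline (so a positive-to-negative
crossing always exists), sampled at 50 Hz.

All randomness is seeded through ``SessionParams.seed``; identical
parameters give bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from strokewave.errors import DataError
from strokewave.signal_model import (
    AccelTrace,
    ForceTrace,
    SensorSpec,
    StrokeEvent,
    StrokeEventSet,
)

ACCEL_FS = 200.0
FORCE_FS = 50.0

#: Recovery baseline force per gate (N); makes the post-drive
#: positive-to-negative zero crossing well defined.
FORCE_BASELINE_N = -5.0

# landmark geometry, as fractions of the stroke period T (or drive time DT)
_CS_LEAD_FRAC = 0.12       # cycle start precedes the catch trough by this * T
_PEAK_POS_FRAC = 0.45      # drive peak position within the drive, * DT
_SIGMA_TROUGH = 0.040      # Gaussian widths, * T
_SIGMA_PEAK = 0.090
_SIGMA_VALLEY = 0.025
_SIGMA_HUMP = 0.055


@dataclass(frozen=True)
class SessionParams:
    """Parameters of one synthetic paired session."""

    n_strokes: int = 100
    stroke_rate_spm: float = 32.0
    stroke_rate_sd_spm: float = 1.5
    drive_fraction: float = 0.42
    trough_depth: float = -4.0        # m/s^2, catch trough
    drive_peak: float = 2.5           # m/s^2
    drive_end_valley: float = -1.5    # m/s^2
    recovery_hump: float = 1.5        # m/s^2
    noise_sd: float = 0.3             # m/s^2 additive white noise
    drift_amplitude: float = 0.0      # optional slow sinusoidal drift (m/s^2)
    n_gates: int = 2
    gate_force_peak_N: float = 600.0
    gate_amp_jitter_frac: float = 0.0
    gate_timing_jitter_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strokes < 2:
            raise DataError("n_strokes must be >= 2")
        if not 0 < self.drive_fraction < 1:
            raise DataError("drive_fraction must be in (0, 1)")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")
        if not 20.0 <= self.stroke_rate_spm <= 60.0:
            raise DataError("stroke_rate_spm must lie in [20, 60]")
        if self.n_gates < 1:
            raise DataError("n_gates must be >= 1")

    def with_(self, **kwargs) -> "SessionParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ClassPreset:
    """Boat-class preset: stroke-rate distribution and session length."""

    name: str
    stroke_rate_spm: float
    stroke_rate_sd_spm: float
    n_strokes: int


#: Boat-class presets (stroke rates and stroke counts by class).
CLASS_PRESETS: dict[str, ClassPreset] = {
    "w8+": ClassPreset("w8+", 37.88, 1.46, 221),
    "w4-": ClassPreset("w4-", 36.72, 1.90, 183),
    "w1x": ClassPreset("w1x", 31.90, 1.61, 181),
}


@dataclass
class PairedSession:
    """A generated acceleration/force pair with its ground truth."""

    name: str
    params: SessionParams
    accel: AccelTrace
    truth: StrokeEventSet
    force: ForceTrace
    truth_metrics: dict = field(default_factory=dict)


def _stroke_periods(p: SessionParams, rng: np.random.Generator) -> np.ndarray:
    rates = rng.normal(p.stroke_rate_spm, p.stroke_rate_sd_spm, p.n_strokes)
    rates = np.clip(rates, 20.0, 60.0)
    return 60.0 / rates


def _landmarks(p: SessionParams, periods: np.ndarray) -> dict[str, np.ndarray]:
    """Nominal landmark times (s) per stroke.

    The first trough is placed one full period into the trace so the
    leading recovery hump is complete; the trace extends one period past
    the last trough.
    """
    taus = np.empty(len(periods))
    taus[0] = periods[0]
    taus[1:] = periods[0] + np.cumsum(periods[:-1])
    dts = p.drive_fraction * periods
    return {
        "hump": taus - _CS_LEAD_FRAC * periods,
        "trough": taus,
        "peak": taus + _PEAK_POS_FRAC * dts,
        "valley": taus + dts,
        "period": periods,
    }


def _compose(t: np.ndarray, lm: dict[str, np.ndarray], p: SessionParams) -> np.ndarray:
    """Sum of Gaussian bumps, evaluated only over each bump's +-6 sigma."""
    out = np.zeros_like(t)
    fs = ACCEL_FS
    specs = [
        ("hump", p.recovery_hump, _SIGMA_HUMP),
        ("trough", p.trough_depth, _SIGMA_TROUGH),
        ("peak", p.drive_peak, _SIGMA_PEAK),
        ("valley", p.drive_end_valley, _SIGMA_VALLEY),
    ]
    for key, amp, sig_frac in specs:
        for mu, period in zip(lm[key], lm["period"]):
            sigma = sig_frac * period
            lo = max(0, int((mu - 6 * sigma) * fs))
            hi = min(len(t), int((mu + 6 * sigma) * fs) + 1)
            if lo < hi:
                out[lo:hi] += amp * np.exp(-((t[lo:hi] - mu) ** 2) / (2 * sigma**2))
    return out


def _exact_extremum(x: np.ndarray, nominal: int, half_window: int, minimum: bool) -> int:
    lo = max(0, nominal - half_window)
    hi = min(len(x), nominal + half_window + 1)
    seg = x[lo:hi]
    return lo + int(np.argmin(seg) if minimum else np.argmax(seg))


def generate_accel_session(p: SessionParams) -> tuple[AccelTrace, StrokeEventSet]:
    """Generate one acceleration session and its ground-truth events.

    Ground truth is taken from the noiseless composite waveform: per
    stroke, the exact hump maximum (C_S), trough minimum (D_S) and valley
    minimum (D_E), found within a narrow window around each nominal
    landmark.  Noise is added afterwards, so truth is noise-independent.
    """
    rng = np.random.default_rng(p.seed)
    periods = _stroke_periods(p, rng)
    lm = _landmarks(p, periods)
    duration = lm["trough"][-1] + periods[-1]
    n = int(round(duration * ACCEL_FS))
    t = np.arange(n) / ACCEL_FS
    clean = _compose(t, lm, p)

    events = []
    for i, period in enumerate(periods):
        w = int(0.06 * period * ACCEL_FS)
        cs = _exact_extremum(clean, int(round(lm["hump"][i] * ACCEL_FS)), w, minimum=False)
        ds = _exact_extremum(clean, int(round(lm["trough"][i] * ACCEL_FS)), w, minimum=True)
        de = _exact_extremum(clean, int(round(lm["valley"][i] * ACCEL_FS)), w, minimum=True)
        events.append(StrokeEvent(cs, ds, de))
    truth = StrokeEventSet(events=events, fs=ACCEL_FS)

    ax = clean.copy()
    if p.drift_amplitude:
        ax += p.drift_amplitude * np.sin(2 * np.pi * t / duration)
    if p.noise_sd > 0:
        ax += rng.normal(0.0, p.noise_sd, n)
    lateral_sd = max(p.noise_sd, 1e-3)
    trace = AccelTrace(
        t0=0.0,
        fs=ACCEL_FS,
        ax=ax,
        ay=rng.normal(0.0, lateral_sd, n),
        az=rng.normal(0.0, lateral_sd, n),
        spec=SensorSpec(sample_rate_hz=ACCEL_FS, range_g=16.0),
    )
    return trace, truth


def generate_force_session(
    p: SessionParams, truth: StrokeEventSet, duration_s: float | None = None
) -> ForceTrace:
    """Generate the paired per-gate oarlock force trace at 50 Hz.

    Each gate carries a half-sine pulse spanning each ground-truth drive
    ``[D_S, D_E]`` (with optional per-gate onset and amplitude jitter) on a
    constant negative recovery baseline.
    """
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 0x0F]))
    ds_t = truth.drive_starts() / truth.fs
    de_t = truth.drive_ends() / truth.fs
    if duration_s is None:
        duration_s = de_t[-1] + (de_t[-1] - de_t[-2] if len(de_t) > 1 else 2.0)
    n = int(round(duration_s * FORCE_FS))
    t = np.arange(n) / FORCE_FS
    gates = []
    for _ in range(p.n_gates):
        f = np.full(n, FORCE_BASELINE_N)
        for t_on, t_off in zip(ds_t, de_t):
            if p.gate_timing_jitter_s > 0:
                t_on = t_on + rng.normal(0.0, p.gate_timing_jitter_s)
                t_off = t_off + rng.normal(0.0, p.gate_timing_jitter_s)
            amp = p.gate_force_peak_N
            if p.gate_amp_jitter_frac > 0:
                amp *= 1.0 + p.gate_amp_jitter_frac * rng.normal()
            d = t_off - t_on
            if d <= 0:
                continue
            lo = max(0, int(np.ceil(t_on * FORCE_FS)))
            hi = min(n, int(np.floor(t_off * FORCE_FS)) + 1)
            if lo < hi:
                f[lo:hi] += amp * np.sin(np.pi * (t[lo:hi] - t_on) / d)
        gates.append(f)
    return ForceTrace(t0=0.0, fs=FORCE_FS, gates=gates)


def generate_session(p: SessionParams, name: str = "session") -> PairedSession:
    """Generate a paired acceleration/force session."""
    accel, truth = generate_accel_session(p)
    force = generate_force_session(p, truth, duration_s=accel.duration_s)
    dt = (truth.drive_ends() - truth.drive_starts()) / truth.fs
    st = np.diff(truth.drive_ends()) / truth.fs
    return PairedSession(
        name=name,
        params=p,
        accel=accel,
        truth=truth,
        force=force,
        truth_metrics={"drive_time": dt, "stroke_time": st},
    )


def generate_cohort(
    presets: list[ClassPreset] | None = None,
    scale: float = 1.0,
    seed: int = 0,
    **overrides,
) -> list[PairedSession]:
    """One paired session per boat-class preset.

    ``scale`` multiplies each preset's stroke count (e.g. 0.1 for quick
    tests); ``overrides`` are forwarded to every session's
    :class:`SessionParams`.
    """
    if presets is None:
        presets = list(CLASS_PRESETS.values())
    if not presets:
        raise DataError("need at least one preset")
    sessions = []
    children = np.random.SeedSequence(seed).spawn(len(presets))
    for preset, ss in zip(presets, children):
        p = SessionParams(
            n_strokes=max(2, int(round(scale * preset.n_strokes))),
            stroke_rate_spm=preset.stroke_rate_spm,
            stroke_rate_sd_spm=preset.stroke_rate_sd_spm,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            **overrides,
        )
        sessions.append(generate_session(p, name=preset.name))
    return sessions
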