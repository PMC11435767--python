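# strokewave

Rowing stroke segmentation from a single hull-mounted accelerometer.

The forward-axis hull acceleration (200 Hz) is decomposed with a 9-level
biorthogonal 4.4 **undecimated wavelet transform** (UWT, à-trous scheme:
full-length, phase-aligned coefficients at every level). The level-3
approximation is negated and peak-searched for **drive starts** (catch
troughs); each stroke segment is searched backwards for the **cycle
start** (last acceleration peak before the catch); and the level-2
approximation yields the **drive end** as the first minimum after the
in-window peak drive acceleration. A parallel oarlock-force pipeline
(50 Hz, per-gate) provides reference features — summed-force peaks, the
first positive-to-negative zero crossing as the force drive end, and a
configurable threshold-crossing drive-time surrogate — and an agreement
module computes ICC (one-way and two-way random, average measures),
Bland–Altman bias / limits of agreement, and OLS regression between the
two systems.

Because no real paired data ship with the package, a synthetic session
generator produces paired acceleration/force sessions with exact
ground-truth event indices (stereotyped per-stroke waveform: recovery
hump, deep catch trough, drive peak, post-drive valley), enabling fully
self-contained end-to-end validation.

## Layout

| module | contents |
| --- | --- |
| `strokewave.signal_model` | domain types (`AccelTrace`, `ForceTrace`, `StrokeEventSet`, …) and CSV/JSON I/O |
| `strokewave.uwt` | undecimated bior4.4 transform: decomposition, phase alignment, reconstruction |
| `strokewave.stroke_detection` | the wavelet feature-detection cascade and stroke metrics |
| `strokewave.force_features` | gate-force summation, force drive ends, threshold drive-time surrogate, cross-system pairing |
| `strokewave.agreement_stats` | ICC / Bland–Altman / regression and report assembly |
| `strokewave.synthetic` | seeded paired-session generator with ground truth, boat-class presets |
| `strokewave.cli` | `strokewave` command-line entry point |

The bior4.4 analysis/synthesis filters are generated at import time from
the maxflat halfband factorization (machine-precision perfect
reconstruction) rather than copied from rounded tables.

## CLI

```sh
# synthetic paired session (boat-class presets: w8+, w4-, w1x)
strokewave simulate --preset w1x --n-strokes 100 --seed 7 \
    --out-imu imu.csv --out-force force.csv --out-truth truth.csv

# stroke detection from an IMU CSV (time, ax, ay, az; m/s^2 or g)
strokewave detect --imu imu.csv --fs 200 --out events.csv --report summary.json

# force reference features (time + one column per gate, newtons)
strokewave force --force force.csv --fs 50 --out force_events.csv

# agreement statistics between the two systems
strokewave compare --events events.csv --force-events force_events.csv \
    --out report.json

# everything in one go
strokewave e2e --preset w8+ --seed 3 --n-strokes 100 --out-dir out/
```

Exit codes: 0 success, 1 data error, 2 usage error. All randomness is
seeded; repeating a command with the same seed reproduces outputs
byte-for-byte.

### Report schema

`report.json` maps group → metric (`drive_time`, `stroke_time`) → a block
with `icc` (`value`, `model`, `F`, `df1`, `df2`, `p`, `ci95`,
`interpretation`), `bland_altman` (`bias`, `sd`, `loa_low`, `loa_high`;
differences are accelerometer − force), and `regression` (`slope`,
`intercept`, `r2`, `p`; force values are the predictor).

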