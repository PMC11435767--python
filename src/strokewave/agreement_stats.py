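"""Cross-system agreement statistics.

Intraclass correlation for average measures (one-way random ICC(1,k) and
two-way random absolute-agreement ICC(2,k), via ANOVA mean squares), a
Bland-Altman bias / limits-of-agreement analysis, and an ordinary
least-squares regression, assembled into a JSON-serializable report per
metric per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from strokewave.errors import DataError

log = logging.getLogger(__name__)

ICC_MODELS = ("one_way", "two_way_random")


@dataclass
class PairedMeasures:
    """Paired per-stroke measurements from two systems (seconds)."""

    a: np.ndarray
    b: np.ndarray
    label: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if len(self.a) != len(self.b):
            raise DataError("paired sequences must have equal length")
        if len(self.a) < 3:
            raise DataError("need at least 3 pairs")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise DataError("non-finite values in paired measures")

    def __len__(self) -> int:
        return len(self.a)


def _mean_squares(x: np.ndarray) -> dict[str, float]:
    """One- and two-way ANOVA mean squares for an n-subjects x k-raters table."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_within = ss_total - ss_rows
    ss_err = ss_total - ss_rows - ss_cols
    return {
        "msr": ss_rows / (n - 1),
        "msw": ss_within / (n * (k - 1)),
        "msc": ss_cols / (k - 1),
        "mse": ss_err / ((n - 1) * (k - 1)),
        "n": n,
        "k": k,
    }


def interpret_icc(value: float) -> str:
    """Qualitative band: <0.50 poor, 0.50-0.75 moderate, 0.75-0.90 good,
    >0.90 excellent (0.90 exactly falls in 'good')."""
    if not -1.0 <= value <= 1.0:
        raise DataError(f"ICC must lie in [-1, 1], got {value}")
    if value > 0.90:
        return "excellent"
    if value >= 0.75:
        return "good"
    if value >= 0.50:
        return "moderate"
    return "poor"


def icc_average_raters(
    p: PairedMeasures, model: str = "two_way_random", alpha: float = 0.05
) -> dict:
    """Average-measures intraclass correlation with F test and 95% CI.

    ``model="one_way"`` gives ICC(1,k); ``model="two_way_random"`` gives
    ICC(2,k) (absolute agreement), with the confidence interval from the
    Satterthwaite-approximated F bounds.  ``k = 2`` raters (the two
    measurement systems).
    """
    if model not in ICC_MODELS:
        raise DataError(f"model must be one of {ICC_MODELS}, got {model!r}")
    x = np.column_stack([p.a, p.b])
    ms = _mean_squares(x)
    n, k = ms["n"], ms["k"]
    msr, msw, msc, mse = ms["msr"], ms["msw"], ms["msc"], ms["mse"]

    if msr <= 0 or (model == "one_way" and msr < 1e-300):
        return _undefined_icc(model, n, k)

    if model == "one_way":
        if msw == 0 and msr == 0:
            return _undefined_icc(model, n, k)
        value = (msr - msw) / msr
        df1, df2 = n - 1, n * (k - 1)
        if msw == 0:
            f_obs, ci = float("inf"), (1.0, 1.0)
            p_value = 0.0
        else:
            f_obs = msr / msw
            fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
            ci = (1 - 1 / fl, 1 - 1 / fu)
            p_value = float(stats.f.sf(f_obs, df1, df2))
        label = "ICC(1,k): one-way random, average of k=2"
    else:
        denom = msr + (msc - mse) / n
        if denom == 0:
            return _undefined_icc(model, n, k)
        value = (msr - mse) / denom
        df1, df2 = n - 1, (n - 1) * (k - 1)
        if mse == 0:
            f_obs, ci = float("inf"), (1.0, 1.0)
            p_value = 0.0
        else:
            f_obs = msr / mse
            ci = _icc2k_ci(msr, msc, mse, n, k, alpha)
            p_value = float(stats.f.sf(f_obs, df1, df2))
        label = "ICC(2,k): two-way random, absolute agreement, average of k=2"

    return {
        "value": float(value),
        "model": model,
        "description": label,
        "F": float(f_obs),
        "df1": int(df1),
        "df2": int(df2),
        "p": p_value,
        "ci95": [float(ci[0]), float(ci[1])],
        "n": int(n),
        "k": int(k),
        "interpretation": interpret_icc(float(np.clip(value, -1.0, 1.0))),
        "defined": True,
    }


def _undefined_icc(model: str, n: int, k: int) -> dict:
    log.warning("ICC undefined: zero between-subject variance")
    return {
        "value": float("nan"),
        "model": model,
        "description": "undefined (zero between-subject variance)",
        "F": float("nan"),
        "df1": n - 1,
        "df2": 0,
        "p": float("nan"),
        "ci95": [float("nan"), float("nan")],
        "n": int(n),
        "k": int(k),
        "interpretation": "undefined",
        "defined": False,
    }


def _icc2k_ci(msr: float, msc: float, mse: float, n: int, k: int, alpha: float) -> tuple[float, float]:
    """McGraw-Wong CI: single-measures bounds with Satterthwaite df, then
    Spearman-Brown stepped up to average measures."""
    icc21 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    a = k * icc21 / (n * (1 - icc21)) if icc21 < 1 else float("inf")
    b = 1 + k * icc21 * (n - 1) / (n * (1 - icc21)) if icc21 < 1 else float("inf")
    if not np.isfinite(a) or not np.isfinite(b):
        return (1.0, 1.0)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower1 = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper1 = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    step = lambda r: r * k / (1 + (k - 1) * r)  # noqa: E731
    return (float(step(lower1)), float(step(upper1)))


def bland_altman(p: PairedMeasures) -> dict:
    """Bias and 95% limits of agreement of the differences ``a - b``."""
    d = p.a - p.b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    return {
        "bias": bias,
        "sd": sd,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "n": len(d),
    }


def regression(p: PairedMeasures) -> dict:
    """Ordinary least squares of ``b`` on ``a``; r^2 is the squared Pearson
    correlation and ``p`` the slope t-test p-value."""
    if np.var(p.a) == 0:
        raise DataError("zero variance in predictor")
    res = stats.linregress(p.a, p.b)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "stderr": float(res.stderr),
        "n": len(p),
    }


def agreement_block(p: PairedMeasures, icc_model: str = "two_way_random") -> dict:
    """ICC + Bland-Altman + regression for one paired metric."""
    return {
        "label": p.label,
        "group": p.group,
        "n_pairs": len(p),
        "icc": icc_average_raters(p, model=icc_model),
        "bland_altman": bland_altman(p),
        "regression": regression(p),
    }


def build_report(measures: list[PairedMeasures], icc_model: str = "two_way_random") -> dict:
    """Assemble one agreement block per (group, metric).

    Returns ``{group: {metric_label: block}}``; raises if any metric has
    fewer than 3 matched pairs (enforced by :class:`PairedMeasures`).
    """
    if not measures:
        raise DataError("no paired measures supplied")
    report: dict[str, dict] = {}
    for p in measures:
        report.setdefault(p.group or "all", {})[p.label or "metric"] = agreement_block(
            p, icc_model=icc_model
        )
    return report


def paired_system_measures(events, force_evts, group: str = "all", t0: float = 0.0,
                           tol_s: float | None = None) -> list[PairedMeasures]:
    """Match accelerometer and force events and form per-metric pairs.

    Accelerometer drive ends are matched to force drive ends by nearest
    time within half the median stroke period (the difference direction is
    fixed as accelerometer minus force throughout).  Drive times pair the
    matched strokes; stroke times pair consecutive matched stroke pairs
    on both systems.

    Parameters
    ----------
    events : StrokeEventSet
        Accelerometer-derived stroke events.
    force_evts : ForceEvents
        Force-derived per-stroke features.
    """
    from strokewave.force_features import pair_events
    from strokewave.stroke_detection import compute_metrics

    metrics = compute_metrics(events)
    accel_de = t0 + events.drive_ends() / events.fs
    pairs, _ = pair_events(accel_de, force_evts.drive_end_times, tol_s)

    a_dt, b_dt = [], []
    if force_evts.drive_times is not None:
        for i, j in pairs:
            if np.isfinite(force_evts.drive_times[j]):
                a_dt.append(metrics.drive_time[i])
                b_dt.append(force_evts.drive_times[j])
    a_st, b_st = [], []
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if i2 == i1 + 1 and j2 == j1 + 1:
            a_st.append(accel_de[i2] - accel_de[i1])
            b_st.append(force_evts.drive_end_times[j2] - force_evts.drive_end_times[j1])

    out = []
    if len(a_dt) >= 3:
        out.append(PairedMeasures(np.array(a_dt), np.array(b_dt), "drive_time", group))
    if len(a_st) >= 3:
        out.append(PairedMeasures(np.array(a_st), np.array(b_st), "stroke_time", group))
    if not out:
        raise DataError("fewer than 3 matched strokes between systems")
    return out
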