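import numpy as np
import pytest

from strokewave.agreement_stats import (
    PairedMeasures,
    bland_altman,
    build_report,
    icc_average_raters,
    interpret_icc,
    paired_system_measures,
    regression,
)
from strokewave.errors import DataError

# ---------------------------------------------------------------------------
# independent oracles (deliberately loop-based, no shared code with the
# implementation)
# ---------------------------------------------------------------------------


def anova_icc_oracle(a, b):
    """Brute-force one-way and two-way ANOVA mean squares and average-rater
    ICCs for an n x 2 table."""
    x = [[float(ai), float(bi)] for ai, bi in zip(a, b)]
    n, k = len(x), 2
    grand = sum(sum(row) for row in x) / (n * k)
    row_means = [sum(row) / k for row in x]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ssb = k * sum((m - grand) ** 2 for m in row_means)
    ssw = sum((x[i][j] - row_means[i]) ** 2 for i in range(n) for j in range(k))
    ssc = n * sum((c - grand) ** 2 for c in col_means)
    sst = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssb - ssc
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc1k = (msb - msw) / msb
    icc2k = (msb - mse) / (msb + (msc - mse) / n)
    return {"icc1k": icc1k, "icc2k": icc2k, "f1": msb / msw, "f2": msb / mse}


def ols_oracle(a, b):
    """Normal-equations OLS of b on a."""
    n = len(a)
    sx = sum(a)
    sy = sum(b)
    sxx = sum(v * v for v in a)
    sxy = sum(u * v for u, v in zip(a, b))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    mx, my = sx / n, sy / n
    r_num = sum((u - mx) * (v - my) for u, v in zip(a, b))
    r_den = (
        sum((u - mx) ** 2 for u in a) * sum((v - my) ** 2 for v in b)
    ) ** 0.5
    r2 = (r_num / r_den) ** 2
    return slope, intercept, r2


class TestIccOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        a = rng.normal(1.0, 0.2, n)
        b = a + rng.normal(0.0, 0.05, n) + rng.normal(0.0, 0.02)
        p = PairedMeasures(a, b)
        oracle = anova_icc_oracle(a, b)
        one = icc_average_raters(p, "one_way")
        two = icc_average_raters(p, "two_way_random")
        assert one["value"] == pytest.approx(oracle["icc1k"], abs=1e-10)
        assert one["F"] == pytest.approx(oracle["f1"], abs=1e-10)
        assert two["value"] == pytest.approx(oracle["icc2k"], abs=1e-10)
        assert two["F"] == pytest.approx(oracle["f2"], abs=1e-10)

    def test_six_subject_fixture(self):
        # frozen fixture; expectations computed with the ANOVA oracle
        a = np.array([0.81, 0.75, 0.93, 0.86, 0.78, 0.90])
        b = np.array([0.80, 0.77, 0.91, 0.88, 0.76, 0.92])
        oracle = anova_icc_oracle(a, b)
        got = icc_average_raters(PairedMeasures(a, b), "two_way_random")
        assert got["value"] == pytest.approx(oracle["icc2k"], abs=1e-12)
        assert got["df1"] == 5
        assert got["df2"] == 5

    def test_identical_raters_icc_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        for model in ("one_way", "two_way_random"):
            got = icc_average_raters(PairedMeasures(a, a.copy()), model)
            assert got["value"] == pytest.approx(1.0)
            assert got["interpretation"] == "excellent"

    def test_large_noise_poor(self):
        rng = np.random.default_rng(99)
        a = rng.normal(1.0, 0.05, 50)
        b = a + rng.normal(0.0, 0.5, 50)  # noise >> signal
        got = icc_average_raters(PairedMeasures(a, b))
        assert got["value"] < 0.5
        assert got["interpretation"] == "poor"

    def test_common_constant_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(1.0, 0.1, 20)
        b = a + rng.normal(0.0, 0.02, 20)
        base = icc_average_raters(PairedMeasures(a, b))["value"]
        shifted = icc_average_raters(PairedMeasures(a + 5.0, b + 5.0))["value"]
        assert shifted == pytest.approx(base, abs=1e-10)

    def test_common_rescaling_behaviour(self):
        # ICC(2,k) is scale-invariant under a COMMON positive rescaling of
        # both raters (all mean squares scale by c^2); verified against the
        # ANOVA oracle rather than assumed
        rng = np.random.default_rng(4)
        a = rng.normal(1.0, 0.1, 20)
        b = a + rng.normal(0.0, 0.02, 20)
        base = icc_average_raters(PairedMeasures(a, b))["value"]
        scaled = icc_average_raters(PairedMeasures(3.0 * a, 3.0 * b))["value"]
        assert scaled == pytest.approx(anova_icc_oracle(3 * a, 3 * b)["icc2k"], abs=1e-12)
        assert scaled == pytest.approx(base, abs=1e-10)

    def test_zero_between_subject_variance_flagged(self):
        p = PairedMeasures(np.full(5, 2.0), np.full(5, 2.0))
        got = icc_average_raters(p)
        assert not got["defined"]
        assert np.isnan(got["value"])

    def test_ci_brackets_value(self):
        rng = np.random.default_rng(8)
        a = rng.normal(1.0, 0.1, 40)
        b = a + rng.normal(0.0, 0.03, 40)
        for model in ("one_way", "two_way_random"):
            got = icc_average_raters(PairedMeasures(a, b), model)
            assert got["ci95"][0] <= got["value"] <= got["ci95"][1]

    def test_unknown_model_rejected(self):
        p = PairedMeasures(np.arange(4.0), np.arange(4.0))
        with pytest.raises(DataError):
            icc_average_raters(p, "two_way_mixed")


class TestInterpretIcc:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.937, "excellent"),
            (0.993, "excellent"),
            (0.881, "good"),
            (0.901, "excellent"),
            (0.90, "good"),  # boundary: '>0.90 = excellent' read literally
            (0.75, "good"),
            (0.74, "moderate"),
            (0.50, "moderate"),
            (0.49, "poor"),
            (-0.2, "poor"),
        ],
    )
    def test_bands(self, value, band):
        assert interpret_icc(value) == band

    def test_out_of_range(self):
        with pytest.raises(DataError):
            interpret_icc(1.5)


class TestBlandAltman:
    def test_identical_zero_bias_zero_loa(self):
        a = np.array([1.0, 2.0, 3.0])
        out = bland_altman(PairedMeasures(a, a.copy()))
        assert out["bias"] == 0.0
        assert out["loa_low"] == out["loa_high"] == 0.0

    def test_constant_offset(self):
        a = np.array([1.0, 2.0, 3.0])
        out = bland_altman(PairedMeasures(a, a + 0.011))
        assert out["bias"] == pytest.approx(-0.011)
        assert out["sd"] == pytest.approx(0.0, abs=1e-15)

    def test_matches_direct_arithmetic(self, rng):
        a = rng.normal(1.0, 0.1, 10)
        b = rng.normal(1.0, 0.1, 10)
        out = bland_altman(PairedMeasures(a, b))
        d = a - b
        mean = sum(d) / len(d)
        sd = (sum((x - mean) ** 2 for x in d) / (len(d) - 1)) ** 0.5
        assert out["bias"] == pytest.approx(mean, abs=1e-12)
        assert out["sd"] == pytest.approx(sd, abs=1e-12)
        assert out["loa_low"] == pytest.approx(mean - 1.96 * sd, abs=1e-12)
        assert out["loa_high"] == pytest.approx(mean + 1.96 * sd, abs=1e-12)

    def test_antisymmetry(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        assert bland_altman(PairedMeasures(a, b))["bias"] == pytest.approx(
            -bland_altman(PairedMeasures(b, a))["bias"]
        )


class TestRegression:
    def test_identity(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        out = regression(PairedMeasures(a, a.copy()))
        assert out["slope"] == pytest.approx(1.0)
        assert out["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert out["r2"] == pytest.approx(1.0)

    def test_exact_affine(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        out = regression(PairedMeasures(a, 2 * a + 3))
        assert out["slope"] == pytest.approx(2.0)
        assert out["intercept"] == pytest.approx(3.0)
        assert out["r2"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        a = rng.normal(0.8, 0.2, n)
        b = 1.1 * a + rng.normal(0.0, 0.05, n)
        out = regression(PairedMeasures(a, b))
        slope, intercept, r2 = ols_oracle(a, b)
        assert out["slope"] == pytest.approx(slope, abs=1e-10)
        assert out["intercept"] == pytest.approx(intercept, abs=1e-10)
        assert out["r2"] == pytest.approx(r2, abs=1e-10)

    def test_r2_is_squared_pearson(self, rng):
        a = rng.normal(size=25)
        b = a + rng.normal(size=25)
        out = regression(PairedMeasures(a, b))
        r = np.corrcoef(a, b)[0, 1]
        assert out["r2"] == pytest.approx(r**2, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            regression(PairedMeasures(np.full(5, 1.0), np.arange(5.0)))


class TestBuildReport:
    def test_identical_inputs_perfect_agreement(self):
        a = np.array([0.8, 0.82, 0.79, 0.85, 0.81])
        m = [
            PairedMeasures(a, a.copy(), "drive_time", "w1x"),
            PairedMeasures(2 * a, 2 * a.copy(), "stroke_time", "w1x"),
        ]
        rep = build_report(m)
        for label in ("drive_time", "stroke_time"):
            block = rep["w1x"][label]
            assert block["icc"]["value"] == pytest.approx(1.0)
            assert block["bland_altman"]["bias"] == 0.0
            assert block["regression"]["r2"] == pytest.approx(1.0)

    def test_three_groups_three_blocks(self, rng):
        m = []
        for g in ("w8+", "w4-", "w1x"):
            a = rng.normal(0.8, 0.05, 10)
            m.append(PairedMeasures(a, a + rng.normal(0, 0.01, 10), "drive_time", g))
        rep = build_report(m)
        assert set(rep) == {"w8+", "w4-", "w1x"}

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            build_report([])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DataError):
            PairedMeasures(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestPairedSystemMeasures:
    def test_end_to_end_measures(self):
        from strokewave.force_features import force_events
        from strokewave.stroke_detection import detect_stroke_events
        from strokewave.synthetic import SessionParams, generate_session

        sess = generate_session(SessionParams(n_strokes=20, stroke_rate_spm=33.0, seed=2))
        events = detect_stroke_events(sess.accel)
        fe = force_events(sess.force)
        measures = paired_system_measures(events, fe, group="test")
        labels = {m.label for m in measures}
        assert labels == {"drive_time", "stroke_time"}
        rep = build_report(measures)
        assert rep["test"]["drive_time"]["icc"]["value"] > 0.5
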