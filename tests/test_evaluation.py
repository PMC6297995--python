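import numpy as np
import pytest
from scipy import stats

from ctvlt.evaluation import (
    bland_altman,
    icc_2_1,
    mean_abs_diff_ci,
    preliminary_split_sd,
    rm_anova_posthoc,
    sample_size_for_mean_ci,
)


class TestMeanAbsDiff:
    def test_identity(self):
        a = np.arange(5.0)
        assert mean_abs_diff_ci(a, a) == (0.0, (0.0, 0.0))

    def test_constant_diffs(self):
        a = np.zeros(4)
        b = np.array([1.0, -1.0, 1.0, -1.0])
        mean, (lo, hi) = mean_abs_diff_ci(a, b)
        assert mean == 1.0 and lo == hi == 1.0

    def test_matches_t_interval_oracle(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(7, 1, 30), rng.normal(7, 1, 30)
        mean, (lo, hi) = mean_abs_diff_ci(a, b)
        d = np.abs(a - b)
        half = stats.t.ppf(0.975, 29) * d.std(ddof=1) / np.sqrt(30)
        assert mean == pytest.approx(d.mean(), rel=1e-12)
        assert (lo, hi) == pytest.approx((d.mean() - half, d.mean() + half), rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mean_abs_diff_ci([1, 2], [1, 2, 3])


class TestICC:
    # classical 6 judges x 4 targets illustration used across the ICC
    # literature
    SF_TABLE = np.array(
        [
            [9, 2, 5, 8],
            [6, 1, 3, 2],
            [8, 4, 6, 8],
            [7, 1, 2, 6],
            [10, 5, 6, 9],
            [6, 2, 4, 7],
        ],
        dtype=float,
    )

    def test_identical_raters_give_one(self):
        col = np.arange(6.0)
        icc, ci = icc_2_1(np.column_stack([col, col, col]))
        assert icc == pytest.approx(1.0)

    def test_matches_mean_squares_oracle(self):
        Y = self.SF_TABLE
        n, k = Y.shape
        # independent oracle: explicit two-way ANOVA table
        grand = Y.mean()
        msr = k * ((Y.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((Y.mean(0) - grand) ** 2).sum() / (k - 1)
        sse = ((Y - Y.mean(1, keepdims=True) - Y.mean(0) + grand) ** 2).sum()
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        icc, _ = icc_2_1(Y)
        assert icc == pytest.approx(expected, rel=1e-12)
        assert icc == pytest.approx(0.29, abs=0.005)  # published value

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        Y = self.SF_TABLE
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(6), 4),
                "rater": np.tile(np.arange(4), 6),
                "score": Y.ravel(),
            }
        )
        res = pg.intraclass_corr(long, "subject", "rater", "score").set_index("Type")
        icc, ci = icc_2_1(Y)
        assert icc == pytest.approx(res.loc["ICC(A,1)", "ICC"], rel=1e-9)
        np.testing.assert_allclose(ci, res.loc["ICC(A,1)", "CI95"], atol=0.01)

    def test_independent_noise_unbiased_near_zero(self):
        """Independent raters: ICC centred on 0 (200-subject panels)."""
        vals = [
            icc_2_1(np.random.default_rng(s).normal(0, 1, (200, 2)))[0]
            for s in range(50)
        ]
        assert abs(np.mean(vals)) < 0.03

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(7, 1, (20, 3))
        assert icc_2_1(Y + 5.0)[0] == pytest.approx(icc_2_1(Y)[0], rel=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            icc_2_1(np.ones((3, 2)))
        bad = np.ones((6, 2))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            icc_2_1(bad)


class TestBlandAltman:
    def test_identity(self):
        a = np.arange(5.0)
        assert bland_altman(a, a) == (0.0, (0.0, 0.0))

    def test_constant_offset(self):
        a = np.arange(5.0)
        bias, (lo, hi) = bland_altman(a + 2.0, a)
        assert bias == 2.0 and lo == hi == 2.0

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(7, 1, 40), rng.normal(7, 1, 40)
        bias, (lo, hi) = bland_altman(a, b)
        d = a - b
        assert bias == pytest.approx(d.mean(), rel=1e-12)
        assert hi - lo == pytest.approx(2 * 1.96 * d.std(ddof=1), rel=1e-12)

    def test_loa_coverage_on_gaussian(self):
        rng = np.random.default_rng(4)
        a = rng.normal(7, 1, 2000)
        b = a + rng.normal(0.3, 0.5, 2000)
        bias, (lo, hi) = bland_altman(a, b)
        coverage = np.mean((a - b >= lo) & (a - b <= hi))
        assert 0.93 <= coverage <= 0.97


class TestRMAnova:
    def test_identical_columns_sentinel(self):
        Y = np.tile(np.random.default_rng(5).normal(0, 1, 20)[:, None], (1, 3))
        res = rm_anova_posthoc(Y)
        assert res["F"] == 0.0 and res["p"] == 1.0

    def test_shifted_column_detected(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(0, 1, (20, 3))
        Y[:, 2] += 10.0
        res = rm_anova_posthoc(Y)
        assert res["p"] < 0.001
        assert res["posthoc"][(0, 2)] < 0.001 and res["posthoc"][(1, 2)] < 0.001

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        Y = rng.normal(0, 1, (15, 3)) + np.array([0.0, 0.3, 0.1])
        res = rm_anova_posthoc(Y)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 3),
                "method": np.tile(np.arange(3), 15),
                "y": Y.ravel(),
            }
        )
        ref = pg.rm_anova(long, dv="y", within="method", subject="subject")
        assert res["F"] == pytest.approx(ref["F"][0], rel=1e-9)
        assert res["p"] == pytest.approx(ref["p_unc"][0], rel=1e-6)

    def test_type_i_error_rate_under_null(self):
        rng = np.random.default_rng(8)
        rejections = sum(
            rm_anova_posthoc(rng.normal(0, 1, (30, 3)))["p"] < 0.05
            for _ in range(1000)
        )
        assert 35 <= rejections <= 65

    def test_validation(self):
        with pytest.raises(ValueError):
            rm_anova_posthoc(np.ones((2, 3)))


class TestSampleSize:
    def test_linear_scan_oracle(self):
        def oracle(sd, hw):
            n = 2
            while stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n) > hw:
                n += 1
            return n

        for sd, hw in [(0.51, 0.10), (1.0, 0.2), (0.3, 0.07)]:
            assert sample_size_for_mean_ci(sd, hw) == oracle(sd, hw)

    def test_tiny_sd_floor(self):
        assert sample_size_for_mean_ci(1e-9, 0.1) == 2

    def test_monotonicity(self):
        grid = [0.2, 0.4, 0.8]
        for hw in (0.05, 0.1):
            ns = [sample_size_for_mean_ci(sd, hw) for sd in grid]
            assert ns == sorted(ns)  # non-decreasing in sd
        for sd in grid:
            ns = [sample_size_for_mean_ci(sd, hw) for hw in (0.05, 0.1, 0.2)]
            assert ns == sorted(ns, reverse=True)  # non-increasing in half-width

    def test_validation(self):
        with pytest.raises(ValueError):
            sample_size_for_mean_ci(0.0, 0.1)
        with pytest.raises(ValueError):
            sample_size_for_mean_ci(0.5, -0.1)


def test_preliminary_split_sd_runs(design_row_sampler):
    rows = design_row_sampler(40, seed=12)
    rng = np.random.default_rng(12)
    y = np.array([5 + 0.5 * r.st for r in rows]) + rng.normal(0, 0.5, 40)
    sd = preliminary_split_sd(rows, y, n_splits=10, seed=0)
    assert 0 < sd < 2
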