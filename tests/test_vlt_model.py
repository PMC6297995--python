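import dataclasses

import numpy as np
import pytest
from scipy import integrate

from ctvlt.dicom_io import AcquisitionMeta
from ctvlt.features import FeatureVector
from ctvlt.vlt_model import (
    CANDIDATES,
    RegressionModel,
    backward_stepwise,
    design_matrix,
    encode_design,
    fit_ols,
    lr_pvalue,
    predict_vlt,
)


class TestEncodeDesign:
    @pytest.mark.parametrize(
        "filt,expected", [("soft-tissue", 0), ("medium-sharp", 1)]
    )
    def test_filter_encoding(self, filt, expected):
        meta = AcquisitionMeta(100.0, 3.0, 300.0, filt, "chest")
        fv = FeatureVector(50.0, 5.0, 70.0, 8.0, 0.4)
        assert encode_design(meta, fv).filter_sharp == expected

    def test_non_finite_feature_rejected(self):
        meta = AcquisitionMeta(100.0, 3.0, 300.0, "soft-tissue", "abdomen")
        fv = FeatureVector(float("nan"), 5.0, 70.0, 8.0, 0.4)
        with pytest.raises(ValueError, match="image_sd"):
            encode_design(meta, fv)


class TestFitOLS:
    def test_exact_interpolation(self, design_row_sampler):
        rows = design_row_sampler(40, seed=0)
        y = [2.0 + 0.5 * r.st for r in rows]
        m = fit_ols(rows, y, ("st",))
        assert m.intercept == pytest.approx(2.0, abs=1e-8)
        assert m.coefficients["st"] == pytest.approx(0.5, abs=1e-8)
        assert m.residual_sd == pytest.approx(0.0, abs=1e-6)

    def test_duplicated_dataset_invariance(self, design_row_sampler):
        rows = design_row_sampler(40, seed=1)
        y = np.random.default_rng(1).normal(7, 1, 40)
        a = fit_ols(rows, y)
        b = fit_ols(rows * 2, np.concatenate([y, y]))
        for name in CANDIDATES:
            assert b.coefficients[name] == pytest.approx(a.coefficients[name], rel=1e-9)

    def test_matches_normal_equations_oracle(self, design_row_sampler):
        rows = design_row_sampler(60, seed=2)
        y = np.random.default_rng(2).normal(7, 1, 60)
        m = fit_ols(rows, y)
        X = design_matrix(rows, CANDIDATES)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert m.intercept == pytest.approx(beta[0], abs=1e-8)
        for j, name in enumerate(CANDIDATES, start=1):
            assert m.coefficients[name] == pytest.approx(beta[j], abs=1e-8)

    def test_matches_statsmodels(self, design_row_sampler):
        sm = pytest.importorskip("statsmodels.api")
        rows = design_row_sampler(60, seed=3)
        y = np.random.default_rng(3).normal(7, 1, 60)
        m = fit_ols(rows, y)
        res = sm.OLS(y, design_matrix(rows, CANDIDATES)).fit()
        np.testing.assert_allclose(
            [m.intercept] + [m.coefficients[n] for n in CANDIDATES],
            res.params, rtol=1e-8,
        )
        assert m.rss == pytest.approx(res.ssr, rel=1e-10)

    def test_rank_deficiency_named(self, design_row_sampler):
        rows = [
            dataclasses.replace(r, fov=r.st) for r in design_row_sampler(30, seed=4)
        ]
        with pytest.raises(ValueError, match="rank"):
            fit_ols(rows, np.ones(30), ("st", "fov"))

    def test_too_few_observations(self, design_row_sampler):
        with pytest.raises(ValueError):
            fit_ols(design_row_sampler(5, seed=5), np.ones(5))


class TestLRTest:
    def test_identical_rss_gives_p_one(self):
        full = RegressionModel(("st", "fov"), 0, {"st": 1, "fov": 1}, 1.0, 10.0, 50)
        red = RegressionModel(("st",), 0, {"st": 1}, 1.0, 10.0, 50)
        assert lr_pvalue(full, red, 50) == 1.0

    def test_matches_chi2_tail_oracle(self):
        full = RegressionModel(("st", "fov"), 0, {"st": 1, "fov": 1}, 1.0, 10.0, 100)
        red = RegressionModel(("st",), 0, {"st": 1}, 1.0, 15.0, 100)
        stat = 100 * np.log(1.5)
        # independent oracle: numerically integrate the chi2(1) density
        pdf = lambda x: np.exp(-x / 2) / np.sqrt(2 * np.pi * x)
        expected, _ = integrate.quad(pdf, stat, np.inf)
        assert lr_pvalue(full, red, 100) == pytest.approx(expected, rel=1e-6)

    def test_non_nested_rejected(self):
        a = RegressionModel(("st",), 0, {"st": 1}, 1.0, 10.0, 50)
        b = RegressionModel(("fov",), 0, {"fov": 1}, 1.0, 10.0, 50)
        with pytest.raises(ValueError):
            lr_pvalue(a, b, 50)


class TestStepwise:
    def test_deterministic_given_seed(self, design_row_sampler):
        rows = design_row_sampler(103, seed=6)
        y = np.random.default_rng(6).normal(7, 1, 103)
        a = backward_stepwise(rows, y, seed=5)
        b = backward_stepwise(rows, y, seed=5)
        assert a.selected == b.selected
        assert a.coefficients == b.coefficients

    def test_recovers_strong_three_variable_model(self, design_row_sampler):
        truth = {"st": 1.2, "effective_mas": 0.02, "variation_hf": 0.4}
        hits = 0
        for rep in range(10):
            rows = design_row_sampler(103, seed=100 + rep)
            rng = np.random.default_rng(200 + rep)
            y = [
                3.0 + sum(b * getattr(r, n) for n, b in truth.items())
                + rng.normal(0, 0.5)
                for r in rows
            ]
            m = backward_stepwise(rows, y, seed=rep)
            hits += set(m.selected) == set(truth)
        assert hits >= 9

    def test_pure_noise_reaches_intercept_only(self, design_row_sampler):
        hits = 0
        for rep in range(10):
            rows = design_row_sampler(103, seed=300 + rep)
            y = np.random.default_rng(400 + rep).normal(0, 1, 103)
            m = backward_stepwise(rows, y, seed=rep)
            hits += m.selected == ()
            if m.selected == ():
                assert "intercept_only" in m.flags
        assert hits >= 6


class TestPredict:
    def test_intercept_only_constant(self, design_row_sampler):
        m = RegressionModel((), 6.5, {}, 0.5, 1.0, 10, flags=("intercept_only",))
        for r in design_row_sampler(3, seed=7):
            assert predict_vlt(m, r) == (6.5, "ok")

    def test_exact_fit_interpolates(self, design_row_sampler):
        rows = design_row_sampler(40, seed=8)
        y = [2.0 + 0.5 * r.st for r in rows]
        m = fit_ols(rows, y, ("st",))
        for r, yi in zip(rows[:5], y[:5]):
            assert predict_vlt(m, r)[0] == pytest.approx(yi, abs=1e-8)

    def test_matches_dot_product_oracle(self, design_row_sampler):
        rows = design_row_sampler(30, seed=9)
        y = np.random.default_rng(9).normal(7, 1, 30)
        m = fit_ols(rows, y)
        r = rows[0]
        expected = m.intercept + sum(
            m.coefficients[n] * getattr(r, n) for n in CANDIDATES
        )
        assert predict_vlt(m, r)[0] == pytest.approx(expected, rel=1e-12)

    def test_clamped_to_search_range(self, design_row_sampler):
        m = RegressionModel((), 99.0, {}, 0.5, 1.0, 10)
        vlt, flag = predict_vlt(m, design_row_sampler(1, seed=10)[0])
        assert (vlt, flag) == (40.0, "clamped")

    def test_missing_variable(self, design_row_sampler):
        m = RegressionModel(("bogus",), 0.0, {"bogus": 1.0}, 0.5, 1.0, 10)
        with pytest.raises(ValueError, match="bogus"):
            predict_vlt(m, design_row_sampler(1, seed=11)[0])
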