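"""Penalized Gamma GAM: bases, fitting, AIC, selection machinery."""

import numpy as np
import pandas as pd
import pytest

from smokecast.basis import SmoothTerm, build_basis
from smokecast.gam import (
    GammaGAM,
    ModelFormula,
    fit_gamma_gam,
    gamma_deviance,
    r2_correlation,
)
from smokecast.selection import (
    CANDIDATE_UNITS,
    enumerate_models,
    make_term,
    split_data,
)


class TestBasis:
    def test_linear_in_null_space_1d(self):
        """A linear function must be reproduced exactly at any smoothing
        level (it lies in the difference penalty's null space)."""
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0, 10, 200))
        y = np.exp(0.5 + 0.2 * x)  # exact Gamma mean, no noise
        df = pd.DataFrame({"y": y, "x": x})
        for lam in (1e-3, 1.0, 1e8):
            res = fit_gamma_gam(ModelFormula("y", (SmoothTerm(("x",)),)), df, lambdas=[lam])
            np.testing.assert_allclose(np.log(res.fittedvalues), 0.5 + 0.2 * x, atol=1e-6)

    def test_centring_leaves_k_minus_1_columns(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.uniform(size=100)})
        for k in (4, 7, 10):
            tb = build_basis(SmoothTerm(("x",), basis_dim=k), df)
            assert tb.columns.shape[1] == k - 1
            np.testing.assert_allclose(tb.columns.sum(axis=0), 0.0, atol=1e-8)

    def test_2d_dimensions_and_centring(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"u": rng.normal(size=200), "v": rng.normal(size=200)})
        tb = build_basis(SmoothTerm(("u", "v"), "isotropic_2d", 20), df)
        assert tb.columns.shape[1] == 19
        np.testing.assert_allclose(tb.columns.sum(axis=0), 0.0, atol=1e-7)
        assert np.all(np.linalg.eigvalsh(tb.penalty) > -1e-8)

    def test_2d_rotation_invariance(self):
        """The isotropic smooth must fit the same surface after rotating the
        (U, V) plane."""
        rng = np.random.default_rng(3)
        n = 400
        u, v = rng.normal(0, 2, n), rng.normal(0, 2, n)
        y = rng.gamma(10, np.exp(1 + 0.3 * np.sin(u) - 0.2 * np.cos(v)) / 10)
        f = ModelFormula("y", (SmoothTerm(("u", "v"), "isotropic_2d", 16),))
        r1 = fit_gamma_gam(f, pd.DataFrame({"y": y, "u": u, "v": v}))
        th = 1.1
        ur, vr = u * np.cos(th) - v * np.sin(th), u * np.sin(th) + v * np.cos(th)
        r2 = fit_gamma_gam(f, pd.DataFrame({"y": y, "u": ur, "v": vr}))
        np.testing.assert_allclose(r1.fittedvalues, r2.fittedvalues, rtol=1e-6)

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame({"y": [1.0] * 50, "x": [2.0] * 50})
        with pytest.raises(ValueError):
            fit_gamma_gam(ModelFormula("y", (SmoothTerm(("x",)),)), df)

    def test_needs_more_rows_than_basis(self):
        df = pd.DataFrame({"y": np.arange(1.0, 9.0), "x": np.arange(8.0)})
        with pytest.raises(ValueError):
            fit_gamma_gam(ModelFormula("y", (SmoothTerm(("x",), basis_dim=10),)), df)


class TestFormula:
    def test_no_shared_predictors(self):
        with pytest.raises(ValueError):
            ModelFormula("y", (SmoothTerm(("x",)), SmoothTerm(("x",))))

    def test_wind_components_joint_only(self):
        with pytest.raises(ValueError):
            ModelFormula("y", (SmoothTerm(("u_coast_aft",)),))

    def test_terms_sorted_for_determinism(self):
        f1 = ModelFormula("y", (SmoothTerm(("a",)), SmoothTerm(("b",))))
        f2 = ModelFormula("y", (SmoothTerm(("b",)), SmoothTerm(("a",))))
        assert f1 == f2 and str(f1) == "y ~ s(a) + s(b)"


class TestFit:
    def test_intercept_only_mean(self, gamma_sim):
        res = fit_gamma_gam(ModelFormula("y", ()), gamma_sim)
        assert res.fittedvalues[0] == pytest.approx(gamma_sim["y"].mean())
        assert res.deviance_explained == pytest.approx(0.0, abs=1e-12)

    def test_glm_limit_matches_statsmodels(self, gamma_sim, gamma_sim_formula):
        """With all smoothing parameters huge, only the penalty null space
        (linear terms) survives; the fit must match an independent Gamma
        GLM."""
        import statsmodels.api as sm

        res = fit_gamma_gam(gamma_sim_formula, gamma_sim, lambdas=[1e10, 1e10])
        X = sm.add_constant(gamma_sim[["x1", "x2"]].to_numpy())
        glm = sm.GLM(
            gamma_sim["y"].to_numpy(), X, family=sm.families.Gamma(sm.families.links.Log())
        ).fit()
        assert abs(res.deviance - glm.deviance) / glm.deviance < 1e-6
        np.testing.assert_allclose(res.fittedvalues, glm.fittedvalues, rtol=1e-5)

    def test_reml_recovers_smooths(self, gamma_sim, gamma_sim_formula):
        res = fit_gamma_gam(gamma_sim_formula, gamma_sim)
        assert res.converged
        assert np.corrcoef(np.log(res.fittedvalues), gamma_sim["eta_true"])[0, 1] > 0.99
        # the linear effect should be shrunk to ~1 effective df
        assert res.edf_by_term["s(x2)"] == pytest.approx(1.0, abs=0.2)

    def test_rejects_nonpositive_response(self):
        df = pd.DataFrame({"y": [1.0, -2.0, 3.0] * 10, "x": np.arange(30.0)})
        with pytest.raises(ValueError):
            GammaGAM(df, ModelFormula("y", (SmoothTerm(("x",), basis_dim=5),)))

    def test_positive_fitted_means(self, gamma_sim, gamma_sim_formula):
        res = fit_gamma_gam(gamma_sim_formula, gamma_sim)
        assert (res.fittedvalues > 0).all()
        assert 0.0 <= res.deviance <= res.null_deviance

    def test_nesting_never_decreases_deviance_explained(self, gamma_sim):
        t1 = SmoothTerm(("x1",), basis_dim=8)
        t2 = SmoothTerm(("x2",), basis_dim=8)
        lam = {"s(x1)": 1.0, "s(x2)": 1.0}
        d1 = fit_gamma_gam(ModelFormula("y", (t1,)), gamma_sim, lambdas=[1.0]).deviance_explained
        d12 = fit_gamma_gam(ModelFormula("y", (t1, t2)), gamma_sim, lambdas=lam).deviance_explained
        assert d12 >= d1 - 1e-10

    def test_summary_mentions_terms(self, gamma_sim, gamma_sim_formula):
        s = fit_gamma_gam(gamma_sim_formula, gamma_sim).summary()
        assert "s(x1)" in s and "AIC" in s


class TestAic:
    def test_identical_fits_identical_aic(self, gamma_sim, gamma_sim_formula):
        a1 = fit_gamma_gam(gamma_sim_formula, gamma_sim, lambdas=[1.0, 1.0]).aic
        a2 = fit_gamma_gam(gamma_sim_formula, gamma_sim, lambdas=[1.0, 1.0]).aic
        assert a1 == a2

    def test_informative_model_beats_intercept(self, gamma_sim, gamma_sim_formula):
        a_full = fit_gamma_gam(gamma_sim_formula, gamma_sim).aic
        a_null = fit_gamma_gam(ModelFormula("y", ()), gamma_sim).aic
        assert a_full < a_null

    def test_pure_noise_term_bounded_penalty(self, gamma_sim):
        """Adding an unrelated smooth changes AIC by a bounded amount."""
        rng = np.random.default_rng(11)
        df = gamma_sim.assign(z=rng.normal(size=len(gamma_sim)))
        t1 = SmoothTerm(("x1",), basis_dim=8)
        tz = SmoothTerm(("z",), basis_dim=8)
        a1 = fit_gamma_gam(ModelFormula("y", (t1,)), df).aic
        a2 = fit_gamma_gam(ModelFormula("y", (t1, tz)), df).aic
        assert abs(a2 - a1) < 25.0


class TestPredict:
    def test_predict_on_training_matches_fitted(self, gamma_sim, gamma_sim_formula):
        res = fit_gamma_gam(gamma_sim_formula, gamma_sim)
        np.testing.assert_allclose(res.predict(gamma_sim), res.fittedvalues, rtol=1e-10)

    def test_intercept_only_constant(self, gamma_sim):
        res = fit_gamma_gam(ModelFormula("y", ()), gamma_sim)
        out = res.predict(gamma_sim.head(5))
        assert np.ptp(out) == 0.0

    def test_missing_column_raises(self, gamma_sim, gamma_sim_formula):
        res = fit_gamma_gam(gamma_sim_formula, gamma_sim)
        with pytest.raises(ValueError, match="x2"):
            res.predict(gamma_sim[["x1"]].head(3))

    def test_extrapolation_flagged(self, gamma_sim, gamma_sim_formula):
        res = fit_gamma_gam(gamma_sim_formula, gamma_sim)
        nd = pd.DataFrame({"x1": [0.5, 99.0], "x2": [0.0, 0.0]})
        _, flags = res.predict_info(nd)
        assert list(flags) == [False, True]


class TestR2:
    def test_perfect_prediction(self):
        x = np.arange(1.0, 20.0)
        assert r2_correlation(x, x) == pytest.approx(1.0)

    def test_affine_invariance(self):
        x = np.arange(1.0, 20.0)
        assert r2_correlation(x, 2.0 + 3.0 * x) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        assert r2_correlation(rng.normal(size=10000), rng.normal(size=10000)) < 0.01

    def test_zero_variance_undefined(self):
        assert np.isnan(r2_correlation(np.ones(10), np.arange(10.0)))


class TestEnumerate:
    def test_full_candidate_set_gives_2048(self):
        formulas = enumerate_models("mean_pm")
        assert len(formulas) == 2**11
        assert any(len(f.terms) == 0 for f in formulas)

    def test_two_units_four_formulas(self):
        assert len(enumerate_models("mean_pm", ["lag_pm", "temperature"])) == 4

    def test_wind_pairs_never_split(self):
        for f in enumerate_models("mean_pm", ["lag_pm", "coastal_wind"]):
            for t in f.terms:
                if "u_coast_aft" in t.variables:
                    assert set(t.variables) == {"u_coast_aft", "v_coast_aft"}

    def test_eleven_candidate_units(self):
        assert len(CANDIDATE_UNITS) == 11
        assert make_term("coastal_wind").basis == "isotropic_2d"


class TestSplit:
    def test_study_row_counts(self):
        rows = pd.DataFrame({"fire_day": pd.date_range("2012-03-01", periods=597), "v": 1.0})
        train, test = split_data(rows, 0.8, seed=1)
        assert (len(train), len(test)) == (477, 120)

    def test_small_split(self):
        rows = pd.DataFrame({"fire_day": pd.date_range("2020-01-01", periods=10), "v": 1.0})
        train, test = split_data(rows, 0.8, seed=0)
        assert (len(train), len(test)) == (8, 2)

    def test_seed_reproducibility_and_partition(self):
        rows = pd.DataFrame({"fire_day": pd.date_range("2020-01-01", periods=50), "v": np.arange(50.0)})
        t1a, t1b = split_data(rows, 0.8, seed=3)
        t2a, t2b = split_data(rows, 0.8, seed=3)
        pd.testing.assert_frame_equal(t1a, t2a)
        pd.testing.assert_frame_equal(t1b, t2b)
        merged = pd.concat([t1a, t1b]).sort_values("fire_day").reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, rows)

    def test_chronological_option(self):
        rows = pd.DataFrame({"fire_day": pd.date_range("2020-01-01", periods=10), "v": 1.0})
        train, test = split_data(rows, 0.8, seed=0, method="chronological")
        assert train["fire_day"].max() < test["fire_day"].min()
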