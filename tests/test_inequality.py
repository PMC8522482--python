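"""Model fits (OLS, offset-Poisson IRLS) and the RII built on them."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import gammaln

from runequity.inequality import (
    fit_ols,
    fit_poisson_glm,
    rii_distance,
    rii_participation,
    rii_series,
)


class TestOls:
    def test_exact_linear_fit(self):
        x = np.arange(10.0)
        fit = fit_ols(x, 2.0 * x + 1.0)
        np.testing.assert_allclose(fit.coefficients, [1.0, 2.0], atol=1e-12)
        assert fit.deviance == pytest.approx(0.0, abs=1e-18)

    def test_constant_response_gives_zero_slope(self):
        fit = fit_ols(np.arange(10.0), np.full(10, 3.0))
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-14)

    def test_matches_normal_equations_and_statsmodels(self, rng):
        x = rng.normal(size=20)
        y = 1.5 - 0.7 * x + rng.normal(scale=0.5, size=20)
        fit = fit_ols(x, y)
        X = np.column_stack([np.ones(20), x])
        beta_ne = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.coefficients, beta_ne, atol=1e-10)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-10)
        np.testing.assert_allclose(fit.standard_errors, ref.bse, rtol=1e-8)
        assert fit.log_likelihood == pytest.approx(ref.llf, rel=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_ols(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError, match="at least 3"):
            fit_ols(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestPoissonGlm:
    def test_two_group_closed_form(self):
        # saturated two-group model: intercept log(m1), group effect log(m2/m1)
        y = np.array([2, 4, 6, 10, 20, 30])  # group means 4 and 20
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        fit = fit_poisson_glm(X, y)
        assert fit.converged
        np.testing.assert_allclose(
            fit.coefficients, [np.log(4.0), np.log(20.0 / 4.0)], atol=1e-8
        )

    def test_all_zero_counts_flagged_nonconverged(self):
        X = np.ones((20, 1))
        fit = fit_poisson_glm(X, np.zeros(20), offset=np.full(20, 7.0))
        assert not fit.converged

    def test_matches_statsmodels_with_offset(self, rng):
        n = 200
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        off = np.log(rng.uniform(500, 2000, n))
        mu = np.exp(-6.0 + 0.3 * x1 - 0.5 * x2 + off)
        y = rng.poisson(mu)
        X = np.column_stack([np.ones(n), x1, x2])
        fit = fit_poisson_glm(X, y, offset=off)
        ref = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
        assert fit.converged
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.standard_errors, ref.bse, rtol=1e-5)
        assert fit.log_likelihood == pytest.approx(ref.llf, rel=1e-8)
        assert fit.aic == pytest.approx(ref.aic, rel=1e-8)

    def test_matches_direct_likelihood_maximiser(self, rng):
        n = 200
        x = rng.normal(size=n)
        off = np.log(rng.uniform(800, 1200, n))
        y = rng.poisson(np.exp(-5.5 - 0.04 * x + off))
        X = np.column_stack([np.ones(n), x])

        def negll(beta):
            eta = X @ beta + off
            return -(y @ eta - np.exp(eta).sum() - gammaln(y + 1).sum())

        opt = minimize(negll, np.zeros(2), method="BFGS")
        fit = fit_poisson_glm(X, y, offset=off)
        np.testing.assert_allclose(fit.coefficients, opt.x, atol=1e-5)

    def test_invalid_inputs(self):
        X = np.column_stack([np.ones(6), [1, 1, 1, 2, 2, 2], [2, 2, 2, 4, 4, 4]])
        with pytest.raises(ValueError, match="rank"):
            fit_poisson_glm(X, np.arange(6))
        with pytest.raises(ValueError, match="nonnegative"):
            fit_poisson_glm(np.ones((3, 1)), np.array([1, -1, 2]))
        with pytest.raises(ValueError, match="finite"):
            fit_poisson_glm(np.ones((3, 1)), np.ones(3), offset=np.array([0.0, np.inf, 0.0]))

    def test_aic_identity(self, rng):
        y = rng.poisson(5.0, size=50)
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        fit = fit_poisson_glm(X, y)
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.log_likelihood)


class TestRii:
    def test_flat_distance_gives_rii_one(self, tiny_areas):
        panel = pd.DataFrame(
            {"area_id": tiny_areas["area_id"], "month": "2015-06", "distance_km": 7.5}
        )
        r = rii_distance(tiny_areas, panel, "2015-06")
        assert r.rii == pytest.approx(1.0)
        assert r.model_slope == pytest.approx(0.0, abs=1e-14)

    def test_constructed_linear_gradient_gives_two(self, tiny_areas):
        # distance exactly linear in deprivation: 20 km at the min score (5),
        # 10 km at the max score (45) -> RII = 2
        imd = tiny_areas["imd_score"].to_numpy()
        slope = (10.0 - 20.0) / (45.0 - 5.0)
        dist = 20.0 + slope * (imd - 5.0)
        panel = pd.DataFrame(
            {"area_id": tiny_areas["area_id"], "month": "2015-06", "distance_km": dist}
        )
        r = rii_distance(tiny_areas, panel, "2015-06")
        assert r.rii == pytest.approx(2.0, abs=1e-12)

    def test_negative_prediction_is_an_error(self, tiny_areas):
        dist = 50.0 - 1.2 * tiny_areas["imd_score"].to_numpy()  # negative at max score
        panel = pd.DataFrame(
            {"area_id": tiny_areas["area_id"], "month": "2015-06", "distance_km": dist}
        )
        with pytest.raises(ValueError, match="nonpositive"):
            rii_distance(tiny_areas, panel, "2015-06")

    def test_participation_closed_form_identity(self, fixture_data):
        areas, fp = fixture_data["areas"], fixture_data["finisher_panel"]
        for month in ["2010-06", "2011-01", "2011-12"]:
            r = rii_participation(areas, fp, month)
            pred_ratio = np.exp(r.model_intercept + r.model_slope * r.imd_min_used) / np.exp(
                r.model_intercept + r.model_slope * r.imd_max_used
            )
            assert r.rii == pytest.approx(pred_ratio, rel=1e-12)

    def test_participation_matches_statsmodels_predictions(self, fixture_data):
        areas, fp = fixture_data["areas"], fixture_data["finisher_panel"]
        month = "2011-07"
        df = fp[fp["month"] == month].merge(areas, on="area_id")
        X = np.column_stack([np.ones(len(df)), df["imd_score"]])
        ref = sm.GLM(
            df["count"].to_numpy(), X, family=sm.families.Poisson(),
            offset=np.log(df["total_pop"].to_numpy(float)),
        ).fit()
        lo, hi = df["imd_score"].min(), df["imd_score"].max()
        expected = np.exp(ref.params[1] * (lo - hi))
        r = rii_participation(areas, fp, month)
        assert r.rii == pytest.approx(expected, rel=1e-6)

    def test_nonconverged_participation_fit_is_an_error(self, tiny_areas):
        panel = pd.DataFrame(
            {"area_id": tiny_areas["area_id"], "month": "2015-06", "count": 0}
        )
        with pytest.raises(RuntimeError, match="converge"):
            rii_participation(tiny_areas, panel, "2015-06")

    def test_series_is_ordered_and_labelled(self, fixture_data):
        areas, fp = fixture_data["areas"], fixture_data["finisher_panel"]
        out = rii_series(areas, fp, ("2010-03", "2010-05"), "participation")
        assert list(out["month"]) == ["2010-03", "2010-04", "2010-05"]
        assert (out["outcome"] == "participation").all()
        assert (out["rii"] > 0).all()

    def test_series_error_carries_month_label(self, tiny_areas):
        panel = pd.DataFrame(
            {"area_id": tiny_areas["area_id"], "month": "2015-06", "count": 1}
        )
        with pytest.raises(ValueError, match="2015-07"):
            rii_series(tiny_areas, panel, ("2015-06", "2015-07"), "participation")

    def test_participation_rii_invariant_to_population_scale(self, fixture_data):
        areas, fp = fixture_data["areas"], fixture_data["finisher_panel"]
        r1 = rii_participation(areas, fp, "2011-07")
        scaled = areas.assign(total_pop=areas["total_pop"] * 10)
        r2 = rii_participation(scaled, fp, "2011-07")
        assert r2.rii == pytest.approx(r1.rii, rel=1e-9)

    def test_distance_rii_invariances(self, tiny_areas):
        # multiplicative rescaling cancels in the ratio of linear predictions,
        # but an additive shift does not
        imd = tiny_areas["imd_score"].to_numpy()
        base = 20.0 - 0.25 * (imd - 5.0)
        month = "2015-06"

        def rii_of(d):
            panel = pd.DataFrame(
                {"area_id": tiny_areas["area_id"], "month": month, "distance_km": d}
            )
            return rii_distance(tiny_areas, panel, month).rii

        assert rii_of(3.0 * base) == pytest.approx(rii_of(base), rel=1e-12)
        assert rii_of(base + 30.0) != pytest.approx(rii_of(base), rel=1e-3)
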