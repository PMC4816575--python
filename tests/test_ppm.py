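"""Presence-only IWLR: design building, fitting, and the point-process limit."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from cloudclim import synthetic as syn
from cloudclim.grid import GeoGrid, GridTransform
from cloudclim.ppm import (
    auc_rank, build_design, compare_models, fit_iwlr, predict_ror,
    sample_background,
)

from conftest import make_grid


class TestBackground:
    def test_single_cell_domain(self):
        mask = np.ones((3, 3), bool)
        mask[1, 1] = False
        g = make_grid(np.zeros((3, 3)), mask=mask)
        pts = sample_background(g, n=50, seed=0)
        assert ((pts["lon"] >= 0.01) & (pts["lon"] <= 0.02)).all()

    def test_fixed_seed_reproducible(self):
        g = make_grid(np.zeros((10, 10)))
        a = sample_background(g, 100, seed=3)
        b = sample_background(g, 100, seed=3)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_uniform_over_blocks(self):
        g = make_grid(np.zeros((20, 20)))
        rejections = 0
        for seed in range(20):
            pts = sample_background(g, 1000, seed=seed)
            counts, _, _ = np.histogram2d(pts["lat"], pts["lon"], bins=10)
            chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
            rejections += stats.chi2.sf(chi2, counts.size - 1) < 0.01
        assert rejections <= 1


class TestBuildDesign:
    def test_linear_plus_square(self):
        X, info = build_design("x + I(x^2)", pd.DataFrame({"x": [3.0]}))
        np.testing.assert_allclose(X[0], [1.0, 3.0, 9.0])
        assert info.names == ["(Intercept)", "x", "I(x^2)"]

    def test_factor_interaction_expansion(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0],
                           "region": ["africa", "americas", "asia"]})
        X, info = build_design("a*region", df)
        assert info.names == ["(Intercept)", "a", "region[americas]",
                              "region[asia]", "a:region[americas]",
                              "a:region[asia]"]
        # row for the reference level keeps only intercept and a
        np.testing.assert_allclose(X[0], [1, 1, 0, 0, 0, 0])
        np.testing.assert_allclose(X[1], [1, 2, 1, 0, 2, 0])

    def test_reference_level_is_first_alphabetically(self):
        df = pd.DataFrame({"region": ["zulu", "africa", "mike"]})
        _, info = build_design("region", df)
        assert info.names == ["(Intercept)", "region[mike]", "region[zulu]"]

    def test_duplicate_column_errors_with_name(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 5.0], "y": [1.0, 2.0, 5.0]})
        with pytest.raises(ValueError, match="y"):
            build_design("x + y", df)

    def test_levels_pinned_for_prediction(self):
        df = pd.DataFrame({"region": ["a", "b", "c"]})
        _, info = build_design("region", df)
        Xnew, _ = build_design("region", pd.DataFrame({"region": ["b"]}),
                               info=info)
        np.testing.assert_allclose(Xnew[0], [1, 1, 0])


class TestFitIWLR:
    def test_intercept_only_closed_form(self):
        Xp = np.ones((50, 1))
        Xb = np.ones((500, 1))
        W = 1e3
        fit = fit_iwlr(Xp, Xb, W=W)
        expected_p = 50 / (50 + W * 500)
        b0 = np.log(expected_p / (1 - expected_p))
        assert fit.coefficients.iloc[0] == pytest.approx(b0, rel=1e-6)

    def test_slope_stable_in_background_weight(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=2000)
        lam = np.exp(0.8 * x)
        pres = rng.random(2000) < lam / lam.max()
        Xp = np.column_stack([np.ones(pres.sum()), x[pres]])
        Xb = np.column_stack([np.ones(2000), x])
        s1 = fit_iwlr(Xp, Xb, W=1e3).coefficients.iloc[1]
        s2 = fit_iwlr(Xp, Xb, W=1e5).coefficients.iloc[1]
        assert abs(s2 - s1) / abs(s1) < 0.01

    def test_matches_discretized_poisson_ppm_mle(self):
        """Independent oracle: directly maximized Poisson PPM likelihood."""
        rng = np.random.default_rng(5)
        cov = rng.normal(size=(20, 20))
        log_lam = 0.5 + 1.2 * cov
        counts = rng.poisson(np.exp(log_lam) / np.exp(log_lam).mean() * 2.0)
        x_pres = np.repeat(cov.ravel(), counts.ravel())

        def neg_ppm_loglik(params):
            b0, b1 = params
            return -(np.sum(b0 + b1 * x_pres)
                     - np.sum(np.exp(b0 + b1 * cov.ravel())))

        mle = optimize.minimize(neg_ppm_loglik, [0.0, 0.0], method="BFGS").x
        Xp = np.column_stack([np.ones(len(x_pres)), x_pres])
        Xb = np.column_stack([np.ones(cov.size), cov.ravel()])
        fit = fit_iwlr(Xp, Xb, W=1e6)
        assert fit.coefficients.iloc[1] == pytest.approx(mle[1], abs=5e-4)

    def test_separation_raises(self):
        # perfectly separable on a narrow covariate scale forces the
        # coefficients to blow up past the separation guard
        Xp = np.column_stack([np.ones(3), [0.1, 0.2, 0.3]])
        Xb = np.column_stack([np.ones(3), [-0.1, -0.2, -0.3]])
        with pytest.raises(RuntimeError):
            fit_iwlr(Xp, Xb, W=1e3)

    def test_slope_recovery_calibration(self):
        """True slope inside the 95% Wald interval in >=90% of seeds."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            cov = rng.normal(size=2500)
            lam = np.exp(1.5 * cov)
            counts = rng.poisson(lam / lam.mean() * 0.4)
            xp = np.repeat(cov, counts)
            Xp = np.column_stack([np.ones(len(xp)), xp])
            Xb = np.column_stack([np.ones(2500), cov])
            fit = fit_iwlr(Xp, Xb, W=1e4)
            se = np.sqrt(fit.cov[1, 1])
            b = fit.coefficients.iloc[1]
            hits += (b - 1.96 * se) <= 1.5 <= (b + 1.96 * se)
        assert hits / n_seeds >= 0.9


class TestAUC:
    def test_rank_auc_equals_trapezoidal_roc(self):
        rng = np.random.default_rng(2)
        pos = rng.normal(1, 1, 300)
        neg = rng.normal(0, 1, 500)
        a1 = auc_rank(pos, neg)
        # trapezoidal ROC integral oracle
        thr = np.sort(np.concatenate([pos, neg]))[::-1]
        tpr = [(pos >= t).mean() for t in thr] + [1.0]
        fpr = [(neg >= t).mean() for t in thr] + [1.0]
        a2 = np.trapezoid(tpr, fpr)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestPredictRor:
    def _fit(self, formula="x", seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=500)
        pres = rng.random(500) < 0.3
        df = pd.DataFrame({"x": x})
        Xp, info = build_design(formula, df[pres])
        Xb, _ = build_design(formula, df, info=info)
        return fit_iwlr(Xp, Xb, W=1e3, design_info=info)

    def test_zero_coefficients_give_uniform_surface(self):
        fit = self._fit()
        fit.coefficients.iloc[:] = 0.0
        ror = predict_ror(fit, pd.DataFrame({"x": np.linspace(-2, 2, 50)}))
        np.testing.assert_allclose(ror, 1.0)

    def test_monotone_in_positive_covariate(self):
        fit = self._fit()
        fit.coefficients.iloc[1] = abs(fit.coefficients.iloc[1]) + 0.5
        xs = np.linspace(-2, 2, 50)
        ror = predict_ror(fit, pd.DataFrame({"x": xs}))
        assert np.all(np.diff(ror) > 0)
        assert ror.max() == pytest.approx(1.0)

    def test_rescaling_preserves_ratios(self):
        fit = self._fit()
        xs = np.array([-1.0, 0.0, 1.0, 2.0])
        ror = predict_ror(fit, pd.DataFrame({"x": xs}))
        b = fit.coefficients.iloc[1]
        expected_ratio = np.exp(b * (xs[1] - xs[0]))
        assert ror[1] / ror[0] == pytest.approx(expected_ratio, rel=1e-9)


class TestCompareModels:
    def test_identical_fits_have_zero_deltas(self):
        fit = TestPredictRor()._fit()
        tab = compare_models({"a": fit, "b": fit}, baseline="a")
        assert (tab[["dAIC", "dBIC", "dAUC", "dCOR"]] == 0).all().all()

    def test_table_sorted_by_bic(self):
        f1 = TestPredictRor()._fit(seed=1)
        f2 = TestPredictRor()._fit("x + I(x^2)", seed=1)
        tab = compare_models({"a": f1, "b": f2}, baseline="a")
        assert list(tab["BIC"]) == sorted(tab["BIC"])

    def test_bic_prefers_model_with_true_covariate(self):
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(200 + seed)
            x = rng.normal(size=1000)
            z = rng.normal(size=1000)  # irrelevant covariate
            lam = np.exp(1.2 * x)
            counts = rng.poisson(lam / lam.mean() * 0.5)
            keep = np.repeat(np.arange(1000), counts)
            df = pd.DataFrame({"x": x, "z": z})
            dfp = df.iloc[keep]
            fits = {}
            for name, formula in (("noise_only", "z"), ("true_cov", "x")):
                Xp, info = build_design(formula, dfp)
                Xb, _ = build_design(formula, df, info=info)
                fits[name] = fit_iwlr(Xp, Xb, W=1e3, design_info=info)
            tab = compare_models(fits, baseline="noise_only").set_index("model")
            wins += tab.loc["true_cov", "dBIC"] < 0
        assert wins / n_seeds >= 0.9
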