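"""ZIB occupancy model: checklist filtering, MCMC correctness, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from cloudclim import synthetic as syn
from cloudclim.grid import GridStack, GridTransform
from cloudclim.occupancy import (
    CellOccurrence, dic, enumerate_z_posterior, evaluate, filter_checklists,
    fit_zib, mpsrf, predict_occurrence, range_size,
)


def make_data(n_cells=400, beta=(-1.0, 2.0), delta=0.5, seed=0, shape=None):
    if shape is None:
        side = int(np.ceil(np.sqrt(n_cells)))
        shape = (side, side)
    cov = syn.generate_covariates(shape, ["x"], seed=seed)
    df, truth = syn.generate_occupancy_data(list(beta), delta, cov, seed=seed)
    return CellOccurrence(df=df, covariate_names=["x"]), truth, cov


class TestFilterChecklists:
    FIXTURE = pd.DataFrame({
        "cell_id":     [1,     1,     1,     2,      2,     3],
        "complete":    [True,  True,  False, True,   True,  True],
        "duration_h":  [2.0,   4.0,   1.0,   3.9,    3.0,   1.0],
        "distance_km": [1.0,   1.0,   1.0,   np.nan, 10.0,  4.0],
        "area_ha":     [np.nan, 10.0, 10.0,  100.0,  200.0, np.nan],
        "detected":    [1,     1,     1,     0,      1,     0],
    })

    def test_four_hour_boundary_is_strict(self):
        agg = filter_checklists(self.FIXTURE)
        # record 2 (4.0 h exactly) must be excluded
        assert agg.set_index("cell_id").loc[1, "n"] == 1

    def test_incomplete_checklists_always_excluded(self):
        df = self.FIXTURE.copy()
        df["duration_h"] = 1.0
        agg = filter_checklists(df).set_index("cell_id")
        assert agg.loc[1, "n"] == 2  # the incomplete record still dropped

    def test_hand_counted_survivors(self):
        agg = filter_checklists(self.FIXTURE).set_index("cell_id")
        # cell 1: records 0 only (1 excluded by 4h, 2 incomplete)
        # cell 2: record 3 (area passes) and 4 (area passes); y = 1
        # cell 3: record 5 (distance passes)
        assert agg.loc[1, "n"] == 1 and agg.loc[1, "y"] == 1
        assert agg.loc[2, "n"] == 2 and agg.loc[2, "y"] == 1
        assert agg.loc[3, "n"] == 1 and agg.loc[3, "y"] == 0


class TestSampler:
    def test_same_seed_identical_draws(self):
        data, _, _ = make_data(100)
        a = fit_zib(data, chains=2, burnin=200, iters=400, thin=4, seed=9)
        b = fit_zib(data, chains=2, burnin=200, iters=400, thin=4, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_kept_draw_count(self):
        data, _, _ = make_data(100)
        d = fit_zib(data, chains=2, burnin=100, iters=300, thin=3, seed=1)
        assert d.samples.shape == (2, 100, 3)

    def test_no_detections_rejected(self):
        data, _, _ = make_data(100)
        df = data.df.copy()
        df["y"] = 0
        with pytest.raises(ValueError, match="detections"):
            fit_zib(CellOccurrence(df=df, covariate_names=["x"]),
                    chains=1, burnin=10, iters=10, thin=1)

    def test_z_conditional_matches_exact_enumeration(self):
        """3-cell toy: MCMC marginal P(z=1 | y=0) vs grid integration."""
        y = np.array([0.0, 0.0, 3.0])
        n = np.array([5.0, 2.0, 4.0])
        x = np.array([-1.0, 0.5, 1.0])
        df = pd.DataFrame({"cell_id": [0, 1, 2], "lon": 0.0, "lat": 0.0,
                           "n": n, "y": y, "x": x})
        data = CellOccurrence(df=df, covariate_names=["x"])
        draws = fit_zib(data, chains=3, burnin=2000, iters=20000, thin=2,
                        seed=4, prior_var=4.0, standardize=False)
        # recompute P(z_i=1|y_i=0) from the kept (beta, gamma) draws:
        # averaging the exact conditional over the posterior gives the
        # marginal; the oracle integrates the same posterior on a grid
        flat = draws.flat()
        X = np.column_stack([np.ones(3), x])
        theta = expit(X @ flat[:, :2].T)
        delta = expit(flat[:, 2])
        odds = theta * (1 - delta) ** n[:, None]
        p_z1 = (odds / (odds + 1 - theta)).mean(axis=1)

        gs = np.linspace(-4, 4, 41)
        bb = np.stack(np.meshgrid(gs, gs), -1).reshape(-1, 2)
        exact = enumerate_z_posterior(y, n, X, bb, gs, prior_var=4.0)
        mc_se = (odds / (odds + 1 - theta)).std(axis=1) / np.sqrt(flat.shape[0] / 10)
        for i in range(2):
            assert abs(p_z1[i] - exact[i]) < np.maximum(3 * mc_se[i], 0.02)

    def test_recovers_generating_parameters(self):
        data, truth, _ = make_data(n_cells=1600, seed=3)
        draws = fit_zib(data, chains=1, burnin=1000, iters=4000, thin=5,
                        seed=5)
        s = draws.summary().set_index("param")
        assert s.loc["beta_x", "q2.5"] < 2.0 < s.loc["beta_x", "q97.5"]
        g = s.loc["gamma"]
        assert g["q2.5"] < 0.0 < g["q97.5"]  # delta = 0.5 -> gamma = 0


class TestDiagnostics:
    def test_degenerate_posterior_gives_zero_pd(self):
        data, _, _ = make_data(100)
        draws = fit_zib(data, chains=1, burnin=200, iters=200, thin=2, seed=2)
        draws.samples[:] = draws.samples[0, 0]  # collapse to a point
        y, n, X_raw = data.arrays()
        from scipy.special import gammaln
        from cloudclim.occupancy import _marginal_deviance
        X = np.column_stack([np.ones(len(y)),
                             (X_raw - draws.cov_means) / draws.cov_sds])
        lb = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
        d0 = _marginal_deviance(y, n, lb, expit(X @ draws.samples[0, 0, :-1]),
                                float(expit(draws.samples[0, 0, -1])))
        draws.deviance[:] = d0
        out = dic(draws, data)
        assert out["pD"] == pytest.approx(0.0, abs=1e-9)
        assert out["DIC"] == pytest.approx(d0, abs=1e-9)

    def test_dic_prefers_true_covariate_model(self):
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cov = syn.generate_covariates((20, 20), ["x", "junk"], seed=seed)
            df, _ = syn.generate_occupancy_data([-0.5, 2.0, 0.0], 0.6, cov,
                                                seed=seed)
            kw = dict(chains=1, burnin=400, iters=1200, thin=3, seed=seed)
            d_true = dic(fit_zib(CellOccurrence(df, ["x"]), **kw),
                         CellOccurrence(df, ["x"]))
            d_junk = dic(fit_zib(CellOccurrence(df, ["junk"]), **kw),
                         CellOccurrence(df, ["junk"]))
            wins += d_true["DIC"] < d_junk["DIC"]
        assert wins / n_seeds >= 0.9

    def test_mpsrf_near_one_for_identical_chains(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=(1000, 3))
        r = mpsrf(np.stack([chain, chain, chain]))
        assert r <= 1.01

    def test_mpsrf_small_for_same_distribution(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(3, 5000, 4))
        assert mpsrf(chains) < 1.1

    def test_mpsrf_large_for_divergent_chains(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(3, 1000, 2))
        chains += np.array([0.0, 3.0, 6.0])[:, None, None]
        assert mpsrf(chains) > 2.0


class TestPrediction:
    def test_zero_beta_draws_predict_half(self):
        data, _, cov = make_data(100)
        draws = fit_zib(data, chains=1, burnin=100, iters=200, thin=2, seed=3)
        draws.samples[..., :-1] = 0.0
        mean, lo, hi = predict_occurrence(draws, cov)
        np.testing.assert_allclose(mean.unmasked_values(), 0.5, atol=1e-12)

    def test_monotone_covariate_monotone_theta(self):
        data, _, cov = make_data(400, seed=6)
        draws = fit_zib(data, chains=1, burnin=400, iters=800, thin=4, seed=6)
        mean, _, _ = predict_occurrence(draws, cov)
        x = cov.as_array()[0].ravel()
        order = np.argsort(x)
        th = mean.values.ravel()[order]
        assert np.all(np.diff(th) >= -1e-12)

    def test_ci_narrows_with_more_data(self):
        widths = []
        for side in (15, 40):
            data, _, cov = make_data(side * side, seed=8, shape=(side, side))
            draws = fit_zib(data, chains=1, burnin=400, iters=1200, thin=3,
                            seed=8)
            mean, lo, hi = predict_occurrence(draws, cov)
            widths.append(np.nanmean(hi.values - lo.values))
        assert widths[1] < widths[0]


class TestRangeSizeAndEvaluate:
    def test_two_half_probability_cells_make_one_cell(self):
        assert range_size(np.array([0.5, 0.5])) == pytest.approx(1.0)

    def test_degenerate_cases(self):
        assert range_size(np.zeros(10)) == 0.0
        assert range_size(np.ones(7)) == 7.0

    def test_linear_in_disjoint_domains(self, rng):
        a = rng.random(50)
        b = rng.random(30)
        assert range_size(np.concatenate([a, b])) == pytest.approx(
            range_size(a) + range_size(b))

    def test_probabilities_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            range_size(np.array([0.5, 1.2]))

    def test_perfect_ranking_gives_auc_one(self):
        theta = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([3, 1, 0, 0])
        n = np.array([5, 5, 5, 5])
        out = evaluate(theta, y, n)
        assert out["AUC"] == 1.0
        assert out["nPresence"] == 2 and out["nTrials"] == 20

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(0)
        theta = rng.random(4000)
        y = (rng.random(4000) < 0.3).astype(int)
        n = np.ones(4000, int)
        auc = evaluate(theta, y, n)["AUC"]
        # SE of AUC ~ sqrt(1/12) * sqrt(1/n1 + 1/n0)
        se = np.sqrt(1 / 12) * np.sqrt(1 / (y > 0).sum() + 1 / (y == 0).sum())
        assert abs(auc - 0.5) < 3 * se

    def test_constant_predictions_warn_and_report_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            out = evaluate(np.full(10, 0.4), np.arange(10) % 2,
                           np.ones(10, int))
        assert np.isnan(out["cor"])
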