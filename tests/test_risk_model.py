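"""Additive logistic risk model: screening, penalized fit, selection, evaluation,
partial dependence and the LOESS sensitivity smoother."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from akiphen.risk_model import (auc_mann_whitney, evaluate_model,
                                fit_additive_model, hosmer_lemeshow, loess_refit,
                                partial_dependence, pirls, stepwise_select,
                                univariable_screen, _local_linear_smooth)
from akiphen.splines import rcs_basis


def expit(z):
    return 1 / (1 + np.exp(-z))


# ---------------------------------------------------------------------------
# univariable screening
# ---------------------------------------------------------------------------

class TestScreen:
    def test_lrt_matches_statsmodels_glm_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        y = np.array([0, 1, 0, 1, 1, 0, 0, 1, 0, 1, 1, 0], float)
        res = univariable_screen(pd.DataFrame({"x": x}), y)
        B = rcs_basis(x, n_knots=3)
        full = sm.GLM(y, sm.add_constant(B), family=sm.families.Binomial()).fit()
        null = sm.GLM(y, np.ones((12, 1)), family=sm.families.Binomial()).fit()
        lrt = null.deviance - full.deviance
        want = stats.chi2.sf(lrt, 2)
        assert res.table.loc[0, "p_value"] == pytest.approx(want, abs=1e-6)

    def test_binary_candidate_equal_to_outcome_flags_separation(self):
        y = np.array([0.0, 1.0] * 20)
        res = univariable_screen(pd.DataFrame({"x": y}), y)
        assert bool(res.table.loc[0, "separation"])
        assert res.table.loc[0, "p_value"] < 0.05  # still informative, not silent

    def test_type_one_error_calibration(self):
        # independent numeric candidate at alpha 0.2: rejection rate stays near 0.2
        rng = np.random.default_rng(1)
        n, reps = 500, 500
        rejections = 0
        for _ in range(reps):
            x = rng.normal(size=n)
            y = (rng.random(n) < 0.4).astype(float)
            res = univariable_screen(pd.DataFrame({"x": x}), y, alpha=0.2)
            rejections += bool(res.table.loc[0, "keep"])
        assert 0.16 <= rejections / reps <= 0.24

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            univariable_screen(pd.DataFrame({"x": np.arange(10.0)}), np.zeros(10))


# ---------------------------------------------------------------------------
# penalized additive fit
# ---------------------------------------------------------------------------

class TestAdditiveFit:
    def test_linear_truth_shrinks_to_one_edf(self):
        rng = np.random.default_rng(2)
        n = 2000
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-0.2 + 1.0 * x)).astype(float)
        m = fit_additive_model(pd.DataFrame({"x": x}), y, smooth_vars=["x"])
        term = m.terms[0]
        assert 1.0 <= term.edf <= 1.6

    def test_zero_penalty_matches_unpenalized_glm(self):
        rng = np.random.default_rng(3)
        n = 120
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(np.sin(x))).astype(float)
        m = fit_additive_model(pd.DataFrame({"x": x}), y, smooth_vars=["x"],
                               lambdas=[0.0])
        B = rcs_basis(x, knots=m.terms[0].knots)
        oracle = sm.GLM(y, sm.add_constant(B), family=sm.families.Binomial()).fit()
        assert m.deviance == pytest.approx(oracle.deviance, abs=1e-6)

    def test_intercept_only_predicts_prevalence(self):
        rng = np.random.default_rng(4)
        y = (rng.random(200) < 0.3).astype(float)
        X = pd.DataFrame({"x": rng.normal(size=200)})
        m = fit_additive_model(X, y)
        np.testing.assert_allclose(m.predict_proba(X), y.mean(), atol=1e-8)

    def test_penalized_objective_monotone_across_iterations(self):
        rng = np.random.default_rng(5)
        n = 300
        D = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        y = (rng.random(n) < expit(D @ np.array([0.2, 1.0, -0.5, 0.0]))).astype(float)
        P = np.diag([0.0, 0.5, 0.5, 0.5])
        _, info = pirls(D, y, P)
        diffs = np.diff(info["pll_trace"])
        assert np.all(diffs >= -1e-10)

    def test_prediction_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(6)
        n = 500
        x = rng.normal(size=n)
        b = (rng.random(n) < 0.5).astype(float)
        y = (rng.random(n) < expit(x - b)).astype(float)
        X1 = pd.DataFrame({"x": x, "b": b})
        X2 = pd.DataFrame({"x": 100.0 + 7.0 * x, "b": b})
        lams = [1.0]
        m1 = fit_additive_model(X1, y, ["x"], ["b"], lambdas=lams,
                                compute_p_values=False)
        m2 = fit_additive_model(X2, y, ["x"], ["b"], lambdas=lams,
                                compute_p_values=False)
        # knots recomputed on the rescaled scale -> same fitted probabilities
        np.testing.assert_allclose(m1.predict_proba(X1), m2.predict_proba(X2),
                                   atol=1e-5)
        assert auc_mann_whitney(y, m1.predict_proba(X1)) == pytest.approx(
            auc_mann_whitney(y, m2.predict_proba(X2)), abs=1e-8)

    def test_binary_outcome_required(self):
        with pytest.raises(ValueError):
            fit_additive_model(pd.DataFrame({"x": np.arange(10.0)}),
                               np.arange(10.0), smooth_vars=["x"])


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

class TestStepwise:
    def test_all_significant_model_unchanged(self, small_model_data):
        X, y = small_model_data
        model, trace = stepwise_select(X[["x1", "b1"]], y, smooth_vars=["x1"],
                                       linear_vars=["b1"], forced=[])
        assert trace == []
        assert set(model.feature_names) == {"x1", "b1"}

    def test_forced_null_term_always_retained(self):
        rng = np.random.default_rng(7)
        n = 600
        X = pd.DataFrame({"signal": rng.normal(size=n),
                          "forced_null": rng.normal(size=n)})
        y = (rng.random(n) < expit(1.2 * X["signal"])).astype(float)
        model, _ = stepwise_select(X, y, smooth_vars=["signal", "forced_null"],
                                   forced=["forced_null"], alpha=0.05)
        assert "forced_null" in model.feature_names
        forced_term = [t for t in model.terms if t.name == "forced_null"][0]
        assert forced_term.p_value > 0.05  # retained despite insignificance

    def test_selection_operating_characteristics(self):
        # 2 signal + 3 noise linear terms, n=1000: signals kept >= 90% of runs,
        # mean retained noise terms <= 0.3
        rng = np.random.default_rng(8)
        reps = 100
        both_kept = 0
        noise_kept = 0
        for _ in range(reps):
            n = 1000
            X = pd.DataFrame(rng.normal(size=(n, 5)),
                             columns=["s1", "s2", "n1", "n2", "n3"])
            y = (rng.random(n) < expit(0.4 * X["s1"] - 0.4 * X["s2"])).astype(float)
            model, _ = stepwise_select(X, y, linear_vars=list(X.columns),
                                       forced=[], alpha=0.05)
            names = set(model.feature_names)
            both_kept += {"s1", "s2"} <= names
            noise_kept += len(names & {"n1", "n2", "n3"})
        assert both_kept >= 0.9 * reps
        assert noise_kept / reps <= 0.3

    def test_empty_candidates_rejected(self, small_model_data):
        X, y = small_model_data
        with pytest.raises(ValueError):
            stepwise_select(X, y, forced=[])
        with pytest.raises(ValueError):
            stepwise_select(X, y, linear_vars=["b1"], forced=["missing"])


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

class TestEvaluation:
    def test_perfect_predictions(self):
        y = np.array([0, 0, 1, 1, 0, 1] * 10, float)
        ev = evaluate_model(y.copy(), pd.DataFrame(index=range(60)), y,
                            n_boot=50, seed=0)
        assert ev.auc == 1.0
        assert ev.hl_statistic == pytest.approx(0.0, abs=1e-10)

    def test_uninformative_predictions_auc_near_half(self):
        rng = np.random.default_rng(9)
        n = 5000
        y = (rng.random(n) < 0.4).astype(float)
        prob = rng.uniform(0.1, 0.9, n)
        ev = evaluate_model(prob, pd.DataFrame(index=range(n)), y, n_boot=50, seed=1)
        assert 0.47 <= ev.auc <= 0.53

    def test_hl_null_p_value_approximately_uniform(self):
        # correctly specified fitted model: HL p across replicates close to uniform
        # (the chi-square df = g-2 reference applies to model-based predictions)
        rng = np.random.default_rng(10)
        pvals = []
        for _ in range(200):
            n = 800
            x = rng.normal(size=n)
            y = (rng.random(n) < expit(0.3 + 0.8 * x)).astype(float)
            beta, _ = pirls(np.column_stack([np.ones(n), x]), y)
            prob = expit(beta[0] + beta[1] * x)
            _, _, p, _ = hosmer_lemeshow(y, prob)
            pvals.append(p)
        d = stats.kstest(pvals, "uniform").statistic
        assert d < 0.1

    def test_hl_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(11)
        n = 20
        prob = np.sort(rng.uniform(0.05, 0.95, n))
        y = (rng.random(n) < prob).astype(float)
        stat, df, _, bins = hosmer_lemeshow(y, prob, n_groups=10)
        # direct formula over the same equal-count groups
        order = np.argsort(prob, kind="mergesort")
        want = 0.0
        for idx in np.array_split(order, 10):
            o, e, ng = y[idx].sum(), prob[idx].sum(), len(idx)
            want += (o - e) ** 2 / (e * (1 - e / ng))
        assert stat == pytest.approx(want, abs=1e-10)
        assert df == 8

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_model(np.full(10, 0.5), pd.DataFrame(index=range(10)),
                           np.zeros(10), n_boot=10)


# ---------------------------------------------------------------------------
# partial dependence
# ---------------------------------------------------------------------------

class TestPartialDependence:
    def test_single_linear_term_gives_affine_logit(self):
        rng = np.random.default_rng(12)
        n = 400
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(0.8 * x)).astype(float)
        X = pd.DataFrame({"x": x})
        m = fit_additive_model(X, y, linear_vars=["x"])
        grid = np.linspace(x.min(), x.max(), 25)
        pd_curve = partial_dependence(m, X, "x", grid)
        logit = np.log(pd_curve["probability"] / (1 - pd_curve["probability"]))
        coeffs = np.polyfit(grid, logit, 1)
        assert np.max(np.abs(np.polyval(coeffs, grid) - logit)) < 1e-8
        assert np.all(np.diff(pd_curve["probability"]) > 0)

    def test_additive_model_pd_equals_term_contribution_plus_constant(self):
        rng = np.random.default_rng(13)
        n = 500
        X = pd.DataFrame({"x": rng.normal(size=n), "z": rng.normal(size=n)})
        y = (rng.random(n) < expit(X["x"] - 0.5 * X["z"])).astype(float)
        m = fit_additive_model(X, y, linear_vars=["x", "z"],
                               compute_p_values=False)
        grid = np.linspace(-1.5, 1.5, 11)
        # on the logit scale, sweeping one variable of a single-patient frame
        # reproduces the fitted term up to the constant from the other terms
        for i in (0, 3):
            probe = X.iloc[[i]].copy()
            etas = []
            for g in grid:
                probe["x"] = g
                etas.append(m.predict_link(probe)[0])
            contrib = [m.term_contribution(pd.DataFrame({"x": [g], "z": [0.0]}),
                                           "x")[0] for g in grid]
            diff = np.array(etas) - np.array(contrib)
            assert np.max(diff) - np.min(diff) < 1e-8

    def test_u_shape_recovered(self):
        rng = np.random.default_rng(14)
        n = 3000
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-0.5 + 0.9 * (x**2 - 1))).astype(float)
        X = pd.DataFrame({"x": x})
        m = fit_additive_model(X, y, smooth_vars=["x"], compute_p_values=False)
        grid = np.linspace(np.quantile(x, 0.05), np.quantile(x, 0.95), 13)
        curve = partial_dependence(m, X, "x", grid)["probability"].to_numpy()
        slopes = np.sign(np.diff(curve))
        changes = np.sum(np.diff(slopes) != 0)
        assert slopes[0] < 0 and slopes[-1] > 0 and changes == 1

    def test_out_of_range_grid_warns(self, small_model_data):
        X, y = small_model_data
        m = fit_additive_model(X[["x1"]], y, smooth_vars=["x1"],
                               compute_p_values=False)
        with pytest.warns(UserWarning):
            partial_dependence(m, X[["x1"]], "x1",
                               np.linspace(X["x1"].min() - 5, X["x1"].max(), 5))


# ---------------------------------------------------------------------------
# LOESS sensitivity refit
# ---------------------------------------------------------------------------

class TestLoess:
    def test_local_linear_smoother_exact_on_lines(self):
        rng = np.random.default_rng(15)
        x = np.sort(rng.uniform(-3, 3, 80))
        y = 2.5 * x - 1.0
        fitted = _local_linear_smooth(x, y, np.ones_like(x), x, span=1.0)
        np.testing.assert_allclose(fitted, y, atol=1e-6)

    def test_agrees_with_spline_fit_on_linear_logit(self):
        rng = np.random.default_rng(16)
        n = 1500
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(1.2 * x)).astype(float)
        X = pd.DataFrame({"x": x})
        spline = fit_additive_model(X, y, smooth_vars=["x"],
                                    compute_p_values=False)
        loess = loess_refit(X, y, smooth_vars=["x"])
        lo, hi = np.quantile(x, [0.1, 0.9])
        grid = np.linspace(lo, hi, 30)
        p1 = partial_dependence(spline, X, "x", grid)["probability"]
        p2 = partial_dependence(loess, X, "x", grid)["probability"]
        assert np.corrcoef(p1, p2)[0, 1] > 0.99

    def test_flat_on_independent_outcome(self):
        rng = np.random.default_rng(17)
        n = 1200
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = (rng.random(n) < 0.5).astype(float)
        loess = loess_refit(X, y, smooth_vars=["x"])
        grid = np.linspace(np.quantile(X["x"], 0.1), np.quantile(X["x"], 0.9), 25)
        curve = partial_dependence(loess, X, "x", grid)["probability"]
        assert curve.max() - curve.min() < 0.05

    def test_tiny_span_rejected(self):
        X = pd.DataFrame({"x": np.arange(30.0)})
        with pytest.raises(ValueError):
            loess_refit(X, np.tile([0.0, 1.0], 15), smooth_vars=["x"], span=0.05)
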