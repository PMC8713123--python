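import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from expowin.pgam import (
    ConvergenceError,
    ModelSpec,
    SeparationError,
    SmoothTermSpec,
    adjusted_r2,
    aic,
    build_basis,
    c_index,
    fit_pgam,
    partial_effect,
    predict,
)
from expowin.pgam.basis import make_term_basis
from expowin._bspline import difference_penalty


def logistic_data(n=300, seed=0, nonlinear=False):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, n)
    eta = 2 * np.sin(2 * np.pi * x) if nonlinear else 0.3 + 1.2 * x
    y = (rng.random(n) < expit(eta)).astype(float)
    return pd.DataFrame({"y": y, "x": x})


class TestBasis:
    def test_penalty_rank_before_constraint(self):
        S = difference_penalty(4, order=2)
        assert np.linalg.matrix_rank(S) == 4 - 2

    def test_constrained_design_columns_sum_to_zero(self):
        x = np.arange(10, dtype=float)
        X, penalties, _ = build_basis(x, SmoothTermSpec(("x",), k=6))
        assert np.allclose(X.sum(axis=0), 0.0, atol=1e-10)

    def test_quadratic_represented_exactly(self):
        x = np.linspace(0, 1, 50)
        y = 1.5 - 2.0 * x + 3.0 * x**2
        X, _, _ = build_basis(x, SmoothTermSpec(("x",), k=6))
        D = np.column_stack([np.ones_like(x), X])
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        assert np.max(np.abs(D @ coef - y)) < 1e-8

    def test_too_few_distinct_values(self):
        x = np.array([0.0, 1.0, 2.0] * 10)
        with pytest.raises(ValueError, match="distinct"):
            build_basis(x, SmoothTermSpec(("x",), k=10))

    def test_k_invariant(self):
        with pytest.raises(ValueError, match="penalty_order"):
            SmoothTermSpec(("x",), k=3, penalty_order=2)

    def test_tensor_term_two_penalties(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame({"u": rng.uniform(0, 1, 60), "v": rng.uniform(0, 1, 60)})
        tb = make_term_basis(SmoothTermSpec(("u", "v"), k=5), data)
        assert len(tb.penalties) == 2
        assert tb.n_coef == 24
        assert np.allclose(tb.design(data).sum(axis=0), 0.0, atol=1e-9)

    def test_double_penalty_adds_null_space_block(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame({"x": rng.uniform(0, 1, 60)})
        tb = make_term_basis(SmoothTermSpec(("x",), k=8, double_penalty=True), data)
        assert len(tb.penalties) == 2
        # null-space penalty annihilated by the range-space penalty directions
        S, S0 = tb.penalties
        assert np.allclose(S @ S0, 0.0, atol=1e-6)


class TestFitLimits:
    def test_lambda_inf_matches_glm(self):
        df = logistic_data(300, seed=1)
        fit = fit_pgam(
            ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)),)), df,
            fixed_lambda=np.inf,
        )
        glm = sm.GLM(
            df["y"], sm.add_constant(df["x"]), family=sm.families.Binomial()
        ).fit()
        assert np.max(np.abs(fit.fitted - glm.fittedvalues)) < 1e-6

    def test_lambda_zero_matches_unpenalized_glm_on_basis(self):
        df = logistic_data(300, seed=2)
        spec = ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",), k=5),))
        fit = fit_pgam(spec, df, fixed_lambda=1e-10)
        X = fit.design.build(df, training=True)
        glm = sm.GLM(df["y"], X, family=sm.families.Binomial()).fit()
        assert np.max(np.abs(fit.fitted - glm.fittedvalues)) < 1e-6

    def test_gaussian_lambda_inf_matches_ols(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 200)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.3, 200)
        df = pd.DataFrame({"y": y, "x": x})
        fit = fit_pgam(
            ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)),), family="gaussian"),
            df, fixed_lambda=np.inf,
        )
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert np.max(np.abs(fit.fitted - ols.fittedvalues)) < 1e-8

    def test_null_simulation_prefers_shrunk_fit(self):
        # pure-noise smooth: REML-selected fit should have small EDF and
        # beat the wiggly lambda->0 fit on AIC in >= 90% of seeds
        better = 0
        small_edf = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 1, 120)
            y = (rng.random(120) < 0.5).astype(float)
            df = pd.DataFrame({"y": y, "x": x})
            spec = ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",), k=8),))
            shrunk = fit_pgam(spec, df)
            from expowin.pgam import FitControl
            wiggly = fit_pgam(
                spec, df, fixed_lambda=1e-8,
                control=FitControl(separation_threshold=200.0),
            )
            if shrunk.aic < wiggly.aic:
                better += 1
            if shrunk.edf_by_term["x"] < 2.5:
                small_edf += 1
        assert better >= int(0.9 * n_seeds)
        assert small_edf >= int(0.9 * n_seeds)


class TestFitInvariants:
    def test_pirls_penalized_deviance_nonincreasing(self):
        df = logistic_data(400, seed=4, nonlinear=True)
        fit = fit_pgam(ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)),)), df)
        trace = np.asarray(fit.pirls_deviance_trace)
        assert np.all(np.diff(trace) <= 1e-8 * (np.abs(trace[:-1]) + 1.0))

    def test_edf_monotone_in_lambda(self):
        df = logistic_data(400, seed=5, nonlinear=True)
        spec = ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)),))
        edfs = [
            fit_pgam(spec, df, fixed_lambda=lam).edf_by_term["x"]
            for lam in (1e-4, 1e-2, 1.0, 1e2, 1e4, 1e6)
        ]
        assert all(a >= b - 1e-6 for a, b in zip(edfs, edfs[1:]))

    def test_aic_invariant_to_covariate_shift(self):
        df = logistic_data(300, seed=6, nonlinear=True)
        spec = ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)),))
        fit1 = fit_pgam(spec, df, fixed_lambda=1.0)
        df2 = df.assign(x=df["x"] + 5.0)
        fit2 = fit_pgam(spec, df2, fixed_lambda=1.0)
        assert fit1.aic == pytest.approx(fit2.aic, abs=1e-6)

    def test_deterministic(self):
        df = logistic_data(200, seed=7, nonlinear=True)
        spec = ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)),))
        a = fit_pgam(spec, df)
        b = fit_pgam(spec, df)
        assert np.array_equal(a.beta, b.beta)

    def test_residual_deviance_below_null(self):
        df = logistic_data(300, seed=8, nonlinear=True)
        fit = fit_pgam(ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)),)), df)
        assert fit.deviance <= fit.null_deviance

    def test_separation_detected(self):
        n = 100
        x = np.concatenate([np.zeros(50), np.ones(50)])
        y = x.copy()
        df = pd.DataFrame({"y": y, "f": np.where(x > 0, "a", "b")})
        with pytest.raises(SeparationError):
            fit_pgam(ModelSpec("y", factor_terms=("f",)), df)

    def test_small_n_rejected(self):
        df = logistic_data(20, seed=9)
        with pytest.raises(ValueError, match="n >= 30"):
            fit_pgam(ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)),)), df)

    def test_single_class_outcome_rejected(self):
        df = logistic_data(100, seed=10).assign(y=0.0)
        with pytest.raises(ValueError):
            fit_pgam(ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)),)), df)

    def test_empty_factor_level_rejected(self):
        df = logistic_data(100, seed=11).assign(f="only")
        with pytest.raises(ValueError, match="levels"):
            fit_pgam(ModelSpec("y", factor_terms=("f",)), df)

    def test_duplicate_covariate_rejected(self):
        with pytest.raises(ValueError, match="twice"):
            ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)),), factor_terms=("x",))


class TestAic:
    def test_aic_identity(self):
        df = logistic_data(200, seed=12, nonlinear=True)
        fit = fit_pgam(ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)),)), df)
        assert aic(fit) == pytest.approx(-2 * fit.loglik + 2 * fit.edf_total)

    def test_unpenalized_nested_pair_matches_lr_identity(self):
        rng = np.random.default_rng(13)
        n = 400
        f = rng.choice(["a", "b", "c"], n)
        g = rng.choice(["u", "v"], n)
        y = (rng.random(n) < expit(0.8 * (f == "a"))).astype(float)
        df = pd.DataFrame({"y": y, "f": f, "g": g})
        small = fit_pgam(ModelSpec("y", factor_terms=("f",)), df)
        big = fit_pgam(ModelSpec("y", factor_terms=("f", "g")), df)
        lr = 2 * (big.loglik - small.loglik)
        ddf = big.edf_total - small.edf_total
        assert small.aic - big.aic == pytest.approx(lr - 2 * ddf, abs=1e-8)

    def test_noise_term_aic_penalty_bound(self):
        df = logistic_data(300, seed=14, nonlinear=True)
        rng = np.random.default_rng(15)
        df["z"] = rng.uniform(0, 1, len(df))
        base = fit_pgam(ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)),)), df)
        bigger = fit_pgam(
            ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)), SmoothTermSpec(("z",)))),
            df,
        )
        loglik_gain = bigger.loglik - base.loglik
        edf_gain = bigger.edf_total - base.edf_total
        assert base.aic - bigger.aic == pytest.approx(2 * loglik_gain - 2 * edf_gain)


class TestPartialEffect:
    def test_lambda_inf_linear_through_zero_at_mean(self):
        df = logistic_data(300, seed=16)
        fit = fit_pgam(
            ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)),)), df,
            fixed_lambda=np.inf,
        )
        pe = partial_effect(fit, "x", grid_size=50)
        # straight line: vanishing second differences
        assert np.max(np.abs(np.diff(pe.effect, 2))) < 1e-6
        # crosses zero at the training covariate mean
        xbar = df["x"].mean()
        val_at_mean = np.interp(xbar, pe.grid, pe.effect)
        assert abs(val_at_mean) < 1e-2 * (pe.effect.max() - pe.effect.min() + 1e-12)

    def test_flag_false_when_band_contains_constant(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame(
            {"y": (rng.random(200) < 0.5).astype(float), "x": rng.uniform(0, 1, 200)}
        )
        fit = fit_pgam(ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)),)), df)
        pe = partial_effect(fit, "x")
        assert pe.significant == (np.max(pe.lo) > np.min(pe.hi))
        assert not pe.significant

    def test_band_halfwidth_linear_algebra_oracle(self):
        df = logistic_data(300, seed=18, nonlinear=True)
        fit = fit_pgam(ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)),)), df)
        pe = partial_effect(fit, "x", grid_size=10)
        tb = fit.design.term_bases["x"]
        sl = fit.design.term_slices["x"]
        for idx in (0, 4, 9):
            g = tb.design(pd.DataFrame({"x": [pe.grid[idx]]}))[0]
            half = 1.96 * np.sqrt(g @ fit.Vb[sl, sl] @ g)
            assert pe.hi[idx] - pe.effect[idx] == pytest.approx(half, rel=1e-10)

    def test_unknown_term_rejected(self):
        df = logistic_data(100, seed=19)
        fit = fit_pgam(ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)),)), df)
        with pytest.raises(KeyError):
            partial_effect(fit, "nope")


class TestPredict:
    def test_training_data_match(self):
        df = logistic_data(200, seed=20, nonlinear=True)
        fit = fit_pgam(ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)),)), df)
        pred = predict(fit, df)
        assert np.allclose(pred.fit, fit.fitted)

    def test_intercept_only_predicts_mean(self):
        df = logistic_data(200, seed=21)
        fit = fit_pgam(ModelSpec("y"), df)
        pred = predict(fit, df.iloc[:5])
        assert np.allclose(pred.fit, df["y"].mean(), atol=1e-8)

    def test_two_point_newdata_manual_dot_product(self):
        df = logistic_data(200, seed=22, nonlinear=True)
        fit = fit_pgam(ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)),)), df)
        new = pd.DataFrame({"x": [0.25, 0.66]})
        pred = predict(fit, new)
        tb = fit.design.term_bases["x"]
        X = np.hstack([np.ones((2, 1)), tb.design(new)])
        eta = X @ fit.beta
        assert np.allclose(pred.eta, eta)
        assert np.allclose(pred.fit, expit(eta))

    def test_unknown_factor_level_rejected(self):
        rng = np.random.default_rng(23)
        df = pd.DataFrame(
            {"y": (rng.random(100) < 0.5).astype(float),
             "f": rng.choice(["a", "b"], 100)}
        )
        fit = fit_pgam(ModelSpec("y", factor_terms=("f",)), df)
        with pytest.raises(ValueError, match="unknown level"):
            predict(fit, pd.DataFrame({"f": ["c"]}))

    def test_extrapolation_warns(self):
        df = logistic_data(200, seed=24)
        fit = fit_pgam(ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)),)), df)
        with pytest.warns(UserWarning, match="outside training range"):
            predict(fit, pd.DataFrame({"x": [2.5]}))


class TestCIndex:
    def test_perfect_ranking(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.8, 0.9])
        assert c_index(p, y) == 1.0

    def test_all_ties(self):
        y = np.array([0, 1, 0, 1])
        p = np.full(4, 0.5)
        assert c_index(p, y) == 0.5

    def test_six_observation_brute_force(self):
        y = np.array([1, 0, 1, 0, 0, 1])
        p = np.array([0.9, 0.4, 0.4, 0.2, 0.9, 0.7])
        num = tot = 0.0
        for i in range(6):
            for j in range(6):
                if y[i] == 1 and y[j] == 0:
                    tot += 1
                    num += 1.0 if p[i] > p[j] else (0.5 if p[i] == p[j] else 0.0)
        assert c_index(p, y) == pytest.approx(num / tot)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(25)
        p = rng.random(50)
        y = (rng.random(50) < 0.4).astype(int)
        assert c_index(p, y) == pytest.approx(c_index(np.exp(3 * p), y))

    def test_bootstrap_ci_contains_estimate(self):
        rng = np.random.default_rng(26)
        p = rng.random(80)
        y = (rng.random(80) < p).astype(int)
        c, (lo, hi) = c_index(p, y, n_boot=200, seed=1)
        assert lo <= c <= hi

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            c_index(np.array([0.2, 0.4]), np.array([1, 1]))


class TestAdjustedR2:
    def test_intercept_only_zero(self):
        df = logistic_data(200, seed=27)
        fit = fit_pgam(ModelSpec("y"), df)
        assert adjusted_r2(fit) == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_gaussian_near_one(self):
        x = np.linspace(0, 1, 200)
        df = pd.DataFrame({"y": np.sin(2 * np.pi * x), "x": x})
        fit = fit_pgam(
            ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",), k=12),), family="gaussian"),
            df,
        )
        assert adjusted_r2(fit) > 0.999

    def test_matches_hand_computation(self):
        df = logistic_data(250, seed=28, nonlinear=True)
        fit = fit_pgam(ModelSpec("y", smooth_terms=(SmoothTermSpec(("x",)),)), df)
        n = fit.n
        expected = 1 - (fit.deviance / (n - fit.edf_total)) / (
            fit.null_deviance / (n - 1)
        )
        assert adjusted_r2(fit) == pytest.approx(expected)


class TestOrTable:
    def test_or_matches_glm_oracle(self):
        rng = np.random.default_rng(29)
        n = 500
        f = rng.choice(["ref", "up"], n)
        y = (rng.random(n) < expit(-0.5 + 1.0 * (f == "up"))).astype(float)
        df = pd.DataFrame({"y": y, "f": f})
        fit = fit_pgam(ModelSpec("y", factor_terms=("f",)), df)
        table = fit.or_table()
        row = table[(table["level"] == "up") & (~table["reference"])].iloc[0]
        glm = sm.GLM(
            y, np.column_stack([np.ones(n), (f == "up").astype(float)]),
            family=sm.families.Binomial(),
        ).fit()
        assert row["OR"] == pytest.approx(np.exp(glm.params[1]), rel=1e-6)
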