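"""Cumulative-logit growth model: probabilities, likelihood, quadrature, fits."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ordgrowth as og
from ordgrowth.model import (
    LOGISTIC_VARIANCE,
    ModelSpec,
    NonMonotoneError,
    ParamVector,
    _Engine,
    _log_expit_diff,
    build_design,
    category_probabilities,
    conditional_loglik,
    fit_mcmc,
    fit_mle,
    icc_latent,
    marginal_loglik,
    nested_init,
)
from ordgrowth.simulate import SimConfig, default_model_spec, default_true_params, simulate_cohort


def _pv(thresholds, shared=(), cat=None, D=None, K=None):
    K = K or len(np.atleast_1d(thresholds)) + 1
    cat = np.zeros((0, K - 1)) if cat is None else np.asarray(cat, float)
    return ParamVector(
        thresholds=np.asarray(thresholds, float),
        shared_coefs=np.asarray(shared, float),
        category_coefs=cat,
        re_cov=np.zeros((2, 2)) if D is None else np.asarray(D, float),
    )


class TestCategoryProbabilities:
    def test_binary_symmetric(self):
        p = category_probabilities(_pv([0.0]))
        assert np.allclose(p, [0.5, 0.5])

    def test_published_threshold_arithmetic(self):
        p = category_probabilities(_pv(np.log([0.02, 19.87, 24.51])))
        assert p[0] == pytest.approx(0.02 / 1.02, abs=1e-6)
        assert p[0] + p[1] == pytest.approx(19.87 / 20.87, abs=1e-6)

    @given(
        st.lists(st.floats(-5, 5), min_size=2, max_size=5),
        st.floats(-3, 3),
        st.floats(-2, 2),
    )
    @settings(max_examples=200, deadline=None)
    def test_probabilities_sum_to_one(self, raw, u0, u1):
        th = np.sort(np.asarray(raw))
        th = th + np.arange(len(th)) * 1e-3  # enforce strict increase
        p = category_probabilities(_pv(th), u=(u0, u1), time=1.3)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)

    def test_non_monotone_raises(self):
        pv = _pv([-1.0, 0.0, 1.0], cat=[[3.0, 0.0, -3.0]])
        with pytest.raises(NonMonotoneError):
            category_probabilities(pv, x_npo=[1.0])


class TestConditionalLoglik:
    def test_single_binary_visit(self, small_bundle):
        df = pd.DataFrame(
            {"stage": [1], "time": [0.0], "x": [0.0]}
        )
        spec = ModelSpec(K=2, shared=("x",))
        ll = conditional_loglik(_pv([0.0], shared=[0.0], K=2), df, u=(0.0, 0.0), spec=spec)
        assert ll == pytest.approx(math.log(0.5))

    def test_two_identical_visits_double(self):
        df1 = pd.DataFrame({"stage": [2], "time": [1.0]})
        df2 = pd.DataFrame({"stage": [2, 2], "time": [1.0, 1.0]})
        spec = ModelSpec(K=4)
        pv = _pv([-1.0, 0.5, 2.0])
        ll1 = conditional_loglik(pv, df1, spec=spec)
        ll2 = conditional_loglik(pv, df2, spec=spec)
        assert ll2 == pytest.approx(2 * ll1, abs=1e-12)

    def test_composes_category_probabilities(self, rng):
        spec = ModelSpec(shared=("x",))
        pv = _pv([-1.0, 0.5, 2.0], shared=[0.7])
        df = pd.DataFrame(
            {
                "stage": rng.integers(1, 5, size=8),
                "time": rng.uniform(0, 3, size=8),
                "x": rng.standard_normal(8),
            }
        )
        u = (0.4, -0.1)
        expected = sum(
            math.log(
                category_probabilities(pv, x_shared=[r.x], time=r.time, u=u)[int(r.stage) - 1]
            )
            for r in df.itertuples()
        )
        assert conditional_loglik(pv, df, u=u, spec=spec) == pytest.approx(expected, abs=1e-10)


class TestMarginalLoglik:
    def test_zero_covariance_is_conditional_at_zero(self, small_cohort):
        spec = default_model_spec()
        b = build_design(small_cohort, spec)
        pv = default_true_params()
        pv0 = ParamVector(pv.thresholds, pv.shared_coefs, pv.category_coefs, np.zeros((2, 2)))
        total = marginal_loglik(pv0, b, quad_order=5)
        by_hand = _Engine(b, 5)._agg(
            _log_expit_diff(*_Engine(b, 5)._eta_bounds(pv0))
        ).sum()
        assert total == pytest.approx(by_hand, abs=1e-9)

    def test_matches_monte_carlo(self, rng):
        # plain MC integration oracle on a 5-subject instance
        cfg = SimConfig(n_subjects=5, visit_rate=1.0, seed=21)
        tab = simulate_cohort(cfg)
        b = build_design(tab, default_model_spec())
        pv = default_true_params()
        eng = _Engine(b, 21)
        ll_q = eng.subject_logliks(pv)
        up, lo = eng._eta_bounds(pv)
        S = 40_000
        L = np.linalg.cholesky(pv.re_cov)
        u = rng.standard_normal((S, 2)) @ L.T
        for i in range(5):
            rows = np.nonzero(b.subject_idx == i)[0]
            llu = np.zeros(S)
            for r in rows:
                shift = u[:, 0] + u[:, 1] * b.time[r]
                llu += _log_expit_diff(up[r] + shift, lo[r] + shift)
            m = llu.max()
            w = np.exp(llu - m)
            mc = m + np.log(w.mean())
            se = w.std() / (w.mean() * np.sqrt(S))
            assert abs(ll_q[i] - mc) < 4 * max(se, 1e-8)

    def test_intercept_only_path_consistent_with_2d(self, small_cohort):
        spec = ModelSpec(shared=("time", "log_vl_c"), random_effects=("intercept",))
        b = build_design(small_cohort, spec)
        pv1 = _pv([-3.9, 3.0, 3.2], shared=[0.1, -0.5], D=[[4.0, 0.0], [0.0, 0.0]])
        pv2 = _pv([-3.9, 3.0, 3.2], shared=[0.1, -0.5], D=[[4.0, 0.0], [0.0, 1e-9]])
        ll1 = marginal_loglik(pv1, b, quad_order=15)
        ll2 = marginal_loglik(pv2, b, quad_order=15)
        assert ll1 == pytest.approx(ll2, abs=1e-5)

    def test_sign_convention_better_stage(self, small_cohort):
        # positive coefficient raises P(Y<=1): mean stage must drop
        spec = ModelSpec(shared=("log_vl_c",))
        pv = _pv([-1.0, 0.5, 2.0], shared=[1.0])
        p_low = category_probabilities(pv, x_shared=[-1.0])
        p_high = category_probabilities(pv, x_shared=[1.0])
        assert p_high[0] > p_low[0]
        assert p_high.cumsum()[2] > p_low.cumsum()[2]


class TestBuildDesign:
    def test_row_count_and_interaction(self, small_cohort):
        spec = ModelSpec(
            shared=("time", "log_vl_c"), npo=("on_cart",), time_interactions=("on_cart",)
        )
        b = build_design(small_cohort, spec)
        assert b.n_rows == len(small_cohort)
        assert b.npo_names == ["on_cart", "on_cart:time"]
        j = b.npo_names.index("on_cart:time")
        expected = small_cohort["on_cart"].to_numpy() * small_cohort["time"].to_numpy()
        assert np.allclose(b.X_npo[:, j], expected)

    def test_empty_npo_reduces_to_po(self, small_bundle):
        assert small_bundle.X_npo.shape[1] == 0

    def test_categorical_reference_expansion(self, small_cohort):
        spec = ModelSpec(
            shared=("education",), categorical_refs={"education": "<=Gr8"}
        )
        b = build_design(small_cohort, spec)
        assert set(b.shared_names) <= {"education[Gr9-10]", "education[>=Gr11]"}

    def test_missing_column_error(self, small_cohort):
        with pytest.raises(ValueError, match="missing columns"):
            build_design(small_cohort, ModelSpec(shared=("nope",)))


class TestFitMLE:
    def test_matches_reference_cumulative_logit_without_random_effects(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        cfg = SimConfig(n_subjects=80, visit_rate=1.0, seed=7)
        tab = simulate_cohort(cfg)
        spec = ModelSpec(shared=("time", "log_vl_c"), random_effects=())
        fit = fit_mle(build_design(tab, spec), quad_order=1, compute_se=False)
        sm = OrderedModel(tab["stage"].astype(int), tab[["time", "log_vl_c"]], distr="logit")
        res = sm.fit(method="bfgs", disp=False)
        ref = np.concatenate(
            [sm.transform_threshold_params(res.params[-3:])[1:-1], -res.params[:2]]
        )
        assert np.max(np.abs(fit.table["estimate"].to_numpy()[:5] - ref)) < 1e-3
        assert fit.minus2loglik == pytest.approx(-2 * res.llf, abs=1e-3)

    def test_npo_never_worse_than_po(self, small_cohort):
        spec_po = ModelSpec(shared=("time", "log_vl_c", "on_cart"))
        spec_npo = ModelSpec(shared=("time", "log_vl_c"), npo=("on_cart",))
        f_po = fit_mle(build_design(small_cohort, spec_po), quad_order=3, compute_se=False)
        b_npo = build_design(small_cohort, spec_npo)
        f_npo = fit_mle(
            b_npo, quad_order=3, compute_se=False, init=nested_init(f_po, b_npo)
        )
        assert f_npo.minus2loglik <= f_po.minus2loglik + 1e-4

    def test_recovers_parameters_on_one_cohort(self):
        cfg = SimConfig(n_subjects=300, visit_rate=1.2, seed=1000)
        tab = simulate_cohort(cfg)
        fit = fit_mle(build_design(tab, default_model_spec()), quad_order=5)
        pv = default_true_params()
        truth = np.concatenate([pv.thresholds, pv.shared_coefs])
        est = fit.table["estimate"].to_numpy()[:7]
        se = fit.table["se"].to_numpy()[:7]
        assert fit.converged
        assert np.all(np.abs(est - truth) < 4 * se)
        assert np.isfinite(fit.minus2loglik)
        assert 0 < fit.icc < 1

    def test_unobserved_category_advises_merge(self, small_cohort):
        tab = small_cohort[small_cohort["stage"] != 3]
        with pytest.raises(ValueError, match="merge"):
            fit_mle(build_design(tab, default_model_spec()), quad_order=3)


class TestICC:
    def test_closed_form_values(self):
        assert icc_latent(LOGISTIC_VARIANCE) == pytest.approx(0.5, abs=1e-15)
        assert icc_latent(0.0) == 0.0
        assert icc_latent(12.21) == pytest.approx(0.7877, abs=5e-5)

    def test_monotone(self):
        grid = [icc_latent(v) for v in (0.1, 1.0, 3.0, 12.21, 100.0)]
        assert all(a < b for a, b in zip(grid, grid[1:]))

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_latent(-0.1)


class TestMCMC:
    def test_posterior_agrees_with_mle(self):
        cfg = SimConfig(n_subjects=50, visit_rate=1.0, seed=33)
        tab = simulate_cohort(cfg)
        spec = ModelSpec(shared=("time", "log_vl_c"), random_effects=("intercept",))
        b = build_design(tab, spec)
        mle = fit_mle(b, quad_order=3)
        post = fit_mcmc(b, quad_order=3, n_iter=1200, burn=400, seed=5, init=mle)
        assert post.dic == pytest.approx(post.dbar + post.p_d, abs=1e-9)
        assert post.p_d > 0
        # posterior medians within 2 Wald SEs of the MLE point estimates
        for name in ("threshold_1", "time", "log_vl_c"):
            row = mle.table[mle.table["name"] == name].iloc[0]
            med = post.table[post.table["name"] == name]["estimate"].iloc[0]
            assert abs(med - row["estimate"]) < 2 * row["se"] + 0.05
        assert 0.05 <= post.acceptance_rate <= 0.7

    def test_posterior_mean_matches_conjugate_toy(self):
        # K=2 with a single covariate and no random effects: the posterior
        # over beta with a diffuse prior should centre near the MLE with
        # matching spread (Bernstein-von Mises at n=400)
        g = np.random.default_rng(3)
        n = 400
        x = g.standard_normal(n)
        eta = 0.8 * x
        y = (g.uniform(size=n) > 1 / (1 + np.exp(-eta))).astype(int) + 1
        tab = pd.DataFrame({"subject_id": np.arange(n), "time": 0.0, "stage": y, "x": x})
        spec = ModelSpec(K=2, shared=("x",), random_effects=())
        b = build_design(tab, spec)
        mle = fit_mle(b, quad_order=1)
        post = fit_mcmc(b, quad_order=1, n_iter=3000, burn=1000, seed=7, init=mle)
        row = mle.table[mle.table["name"] == "x"].iloc[0]
        draws = post.draws["x"].to_numpy()
        mc_se = draws.std() / np.sqrt(len(draws) / 10)  # crude ESS guard
        assert abs(draws.mean() - row["estimate"]) < 3 * max(mc_se, 0.02)
        assert draws.std() == pytest.approx(row["se"], rel=0.4)
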