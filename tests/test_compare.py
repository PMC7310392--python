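"""Likelihood-ratio proportionality test, DIC comparison, report tables."""
import numpy as np
import pandas as pd
import pytest

from ordgrowth.compare import (
    compare_dic,
    lr_proportionality_test,
    odds_ratio_table,
)
from ordgrowth.model import (
    FitResult,
    ModelSpec,
    ParamVector,
    PosteriorFit,
    build_design,
    fit_mle,
    nested_init,
)
from ordgrowth.simulate import SimConfig, simulate_cohort


def _fake_fit(spec, names, kinds, logits, estimates, ses, minus2loglik, icc=0.5):
    est = np.asarray(estimates, float)
    se = np.asarray(ses, float)
    z = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
    from scipy.stats import norm

    table = pd.DataFrame(
        {
            "name": names,
            "kind": kinds,
            "logit": logits,
            "estimate": est,
            "se": se,
            "ci_low": est - 1.959963984540054 * se,
            "ci_high": est + 1.959963984540054 * se,
            "p_value": 2 * norm.sf(np.abs(z)),
        }
    )
    return FitResult(
        params=ParamVector(thresholds=np.array([-1.0, 0.0, 1.0])),
        table=table,
        minus2loglik=minus2loglik,
        converged=True,
        n_iter=10,
        grad_norm=1e-7,
        icc=icc,
        quad_order=5,
        spec=spec,
        theta=est.copy(),
    )


def _po_npo_specs(n_npo=1):
    npo = tuple(f"x{i}" for i in range(n_npo))
    spec_npo = ModelSpec(shared=("time",), npo=npo)
    spec_po = ModelSpec(shared=("time",) + npo, npo=())
    return spec_po, spec_npo


def _fit_pair(n_npo=1, stat=0.0):
    spec_po, spec_npo = _po_npo_specs(n_npo)
    po_names = ["threshold_1", "time"] + [f"x{i}" for i in range(n_npo)]
    po = _fake_fit(
        spec_po,
        po_names,
        ["threshold", "shared"] + ["shared"] * n_npo,
        [1, 0] + [0] * n_npo,
        np.zeros(len(po_names)),
        np.ones(len(po_names)) * 0.1,
        1000.0,
    )
    npo_names = ["threshold_1", "time"] + [
        f"x{i}|logit{k}" for i in range(n_npo) for k in (1, 2, 3)
    ]
    npo = _fake_fit(
        spec_npo,
        npo_names,
        ["threshold", "shared"] + ["npo"] * (3 * n_npo),
        [1, 0] + [1, 2, 3] * n_npo,
        np.zeros(len(npo_names)),
        np.ones(len(npo_names)) * 0.1,
        1000.0 - stat,
    )
    return po, npo


class TestLRTest:
    def test_identical_fits_give_zero(self):
        po, npo = _fit_pair(stat=0.0)
        res = lr_proportionality_test(po, npo)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert not res.reject

    @pytest.mark.parametrize("m, df", [(1, 2), (2, 4), (18, 36)])
    def test_df_counts_freed_coefficients(self, m, df):
        po, npo = _fit_pair(n_npo=m, stat=1.0)
        assert lr_proportionality_test(po, npo).df == df

    def test_negative_statistic_beyond_tolerance_rejected(self):
        po, npo = _fit_pair(stat=-0.01)
        with pytest.raises(ValueError, match="refit"):
            lr_proportionality_test(po, npo)

    def test_non_nested_specs_error(self):
        po, npo = _fit_pair()
        po.spec = ModelSpec(shared=("time", "other"), npo=())
        with pytest.raises(ValueError, match="nested"):
            lr_proportionality_test(po, npo)

    def test_statistic_invariant_to_covariate_rescaling(self, small_cohort):
        spec_po = ModelSpec(shared=("time", "log_vl_c", "on_cart"))
        spec_npo = ModelSpec(shared=("time", "log_vl_c"), npo=("on_cart",))

        def stat_for(tab):
            f_po = fit_mle(build_design(tab, spec_po), quad_order=3, compute_se=False)
            b = build_design(tab, spec_npo)
            f_npo = fit_mle(b, quad_order=3, compute_se=False, init=nested_init(f_po, b))
            return lr_proportionality_test(f_po, f_npo).statistic

        s1 = stat_for(small_cohort)
        doubled = small_cohort.assign(log_vl_c=small_cohort["log_vl_c"] * 2.0)
        s2 = stat_for(doubled)
        assert abs(s1 - s2) < 1e-3


def _fake_post(dbar, p_d, converged=True):
    table = pd.DataFrame(
        {
            "name": ["threshold_1"],
            "kind": ["threshold"],
            "logit": [1],
            "estimate": [0.0],
            "ci_low": [-1.0],
            "ci_high": [1.0],
            "p_value": [0.5],
        }
    )
    return PosteriorFit(
        draws=pd.DataFrame({"threshold_1": [0.0]}),
        theta_draws=np.zeros((1, 1)),
        logliks=np.array([-dbar / 2]),
        acceptance_rate=0.3,
        dbar=dbar,
        p_d=p_d,
        dic=dbar + p_d,
        median_params=ParamVector(thresholds=np.array([0.0])),
        table=table,
        converged=converged,
        warnings=[] if converged else ["acceptance rate 0.05 outside [0.1, 0.6]"],
        spec=ModelSpec(),
        icc=None,
    )


class TestDIC:
    def test_identical_models_zero_delta(self):
        rep = compare_dic(_fake_post(100.0, 5.0), _fake_post(100.0, 5.0))
        assert rep.delta_dic == 0.0
        assert (rep.models["dic"] == rep.models["dbar"] + rep.models["pD"]).all()

    def test_lower_dic_preferred(self):
        rep = compare_dic(_fake_post(100.0, 5.0), _fake_post(90.0, 5.0))
        assert rep.preferred == "non_proportional_odds"
        assert rep.delta_dic == pytest.approx(10.0)

    def test_degenerate_chain_dic_equals_dbar(self):
        rep = compare_dic(_fake_post(100.0, 0.0), _fake_post(90.0, 0.0))
        assert (rep.models["dic"] == rep.models["dbar"]).all()

    def test_unconverged_chain_blocks_preference(self):
        rep = compare_dic(_fake_post(100.0, 5.0), _fake_post(90.0, 5.0, converged=False))
        assert rep.preferred is None
        assert any("converge" in w for w in rep.warnings)


class TestOddsRatioTable:
    def test_zero_coefficient_confidence_interval(self):
        po, _ = _fit_pair()
        tab = odds_ratio_table(po)
        cell = tab[tab["effect"] == "time"]["logit1"].iloc[0]
        assert cell.startswith("1.00 (0.82, 1.22)")

    def test_threshold_reported_as_exponential(self):
        spec = ModelSpec(shared=())
        fit = _fake_fit(
            spec,
            ["threshold_1"],
            ["threshold"],
            [1],
            [np.log(0.02)],
            [0.5],
            100.0,
        )
        tab = odds_ratio_table(fit)
        assert tab[tab["effect"] == "threshold_1"]["logit1"].iloc[0].startswith("0.02")

    def test_shared_effect_repeats_across_logits(self):
        po, npo = _fit_pair()
        tab = odds_ratio_table(po)
        row = tab[tab["effect"] == "time"].iloc[0]
        assert row["logit1"] == row["logit2"] == row["logit3"]
        # npo effects get one cell per logit
        tab_npo = odds_ratio_table(npo)
        row = tab_npo[tab_npo["effect"] == "x0"].iloc[0]
        assert row["logit1"] != "" and row["logit2"] != "" and row["logit3"] != ""

    def test_model_diagnosis_rows_present(self):
        po, _ = _fit_pair()
        tab = odds_ratio_table(po)
        effects = set(tab["effect"])
        assert {"ICC", "-2 log L"} <= effects
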