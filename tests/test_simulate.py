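"""Synthetic cohort generator: covariates, visit process, ordinal outcomes."""
import io

import numpy as np
import pandas as pd
import pytest

from ordgrowth.model import ModelSpec, NonMonotoneError, ParamVector
from ordgrowth.simulate import (
    SimConfig,
    default_model_spec,
    default_true_params,
    simulate_clinical_panel,
    simulate_cohort,
    simulate_ordinal_outcomes,
    simulate_subjects,
    simulate_visits,
    write_cohort,
)
from ordgrowth.staging import who_stage_codes


def _flat_params(thresholds, re_cov=None, shared=0):
    return ParamVector(
        thresholds=np.asarray(thresholds, dtype=float),
        shared_coefs=np.zeros(shared),
        category_coefs=np.zeros((0, len(thresholds))),
        re_cov=np.zeros((2, 2)) if re_cov is None else np.asarray(re_cov, dtype=float),
    )


class TestSubjects:
    def test_default_cohort_size(self):
        subs = simulate_subjects(SimConfig(seed=0))
        assert len(subs) == 219

    def test_zero_covariance_degenerate(self):
        cfg = SimConfig(n_subjects=50, true_params=_flat_params([-1, 0, 1]), seed=1)
        subs = simulate_subjects(cfg)
        assert (subs["u0"] == 0).all() and (subs["u1"] == 0).all()

    def test_random_effect_covariance_recovery(self):
        # large-sample check against the generator's own target D
        D = np.array([[12.21, -0.36], [-0.36, 0.02]])
        cfg = SimConfig(n_subjects=50_000, true_params=_flat_params([-1, 0, 1], D), seed=2)
        subs = simulate_subjects(cfg)
        u = subs[["u0", "u1"]].to_numpy()
        S = np.cov(u, rowvar=False)
        n = len(u)
        se = np.sqrt(
            np.array(
                [
                    [2 * D[0, 0] ** 2, D[0, 0] * D[1, 1] + D[0, 1] ** 2],
                    [D[0, 0] * D[1, 1] + D[0, 1] ** 2, 2 * D[1, 1] ** 2],
                ]
            )
            / n
        )
        assert np.all(np.abs(S - D) < 3 * se)

    def test_covariate_frequencies(self):
        cfg = SimConfig(n_subjects=20_000, seed=3)
        subs = simulate_subjects(cfg)
        p = 178 / 219
        freq = (subs["age_group"] == "21-39").mean()
        assert abs(freq - p) < 3 * np.sqrt(p * (1 - p) / 20_000)

    def test_non_psd_covariance_rejected(self):
        bad = _flat_params([-1, 0, 1], [[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semidefinite"):
            simulate_subjects(SimConfig(n_subjects=5, true_params=bad, seed=0))


class TestVisits:
    def test_zero_followup_baseline_only(self):
        cfg = SimConfig(n_subjects=25, max_followup=0.0, seed=4)
        tab = simulate_visits(simulate_subjects(cfg), cfg)
        assert len(tab) == 25
        assert (tab["time"] == 0).all()

    def test_followup_capped_at_maximum(self):
        cfg = SimConfig(n_subjects=300, seed=5)
        tab = simulate_visits(simulate_subjects(cfg), cfg)
        assert tab["time"].max() <= 13.13
        assert tab.groupby("subject_id")["time"].min().eq(0).all()

    def test_poisson_visit_count_mean(self):
        # fixed 10-year window at rate 2/year: 1 + Poisson(20) visits
        cfg = SimConfig(
            n_subjects=10_000,
            max_followup=10.0,
            visit_rate=2.0,
            followup={"kind": "fixed"},
            seed=6,
        )
        tab = simulate_visits(simulate_subjects(cfg), cfg)
        mean_visits = len(tab) / 10_000
        assert abs(mean_visits - 21.0) < 3 * np.sqrt(20.0 / 10_000)

    def test_phase_from_time(self):
        cfg = SimConfig(n_subjects=200, seed=7)
        tab = simulate_visits(simulate_subjects(cfg), cfg)
        t = tab["time"].to_numpy()
        ph = tab["phase"].to_numpy()
        assert np.all(ph[t < 0.25] == "II")
        assert np.all(ph[(t >= 0.25) & (t < 1.0)] == "III")
        assert np.all(ph[t >= 1.0] == "IV")


class TestOutcomes:
    def test_uniform_category_frequencies(self):
        # flat model: delta at logits of (.25,.5,.75) -> 4 equal categories
        delta = [np.log(p / (1 - p)) for p in (0.25, 0.5, 0.75)]
        cfg = SimConfig(
            n_subjects=12_000,
            max_followup=0.0,
            true_params=_flat_params(delta, shared=4),
            seed=8,
        )
        tab = simulate_cohort(cfg)
        freq = tab["stage"].value_counts(normalize=True).sort_index()
        se = 3 * np.sqrt(0.25 * 0.75 / 12_000)
        assert np.all(np.abs(freq.to_numpy() - 0.25) < se)

    def test_published_threshold_marginal(self):
        # exp(delta) = (0.02, ...) at zero covariates: P(stage 1) = 0.02/1.02
        cfg = SimConfig(
            n_subjects=30_000,
            max_followup=0.0,
            true_params=_flat_params(np.log([0.02, 19.87, 24.51]), shared=4),
            seed=9,
        )
        tab = simulate_cohort(cfg)
        p1 = (tab["stage"] == 1).mean()
        target = 0.02 / 1.02
        assert abs(p1 - target) < 3 * np.sqrt(target * (1 - target) / 30_000)

    def test_saturated_threshold_all_normal(self):
        cfg = SimConfig(
            n_subjects=200,
            true_params=_flat_params([30.0, 31.0, 32.0], shared=4),
            seed=10,
        )
        tab = simulate_cohort(cfg)
        assert (tab["stage"] == 1).all()

    def test_cd4_round_trips_through_staging(self, small_cohort):
        ok = small_cohort["cd4"].notna()
        codes = who_stage_codes(small_cohort.loc[ok, "cd4"].to_numpy())
        assert np.array_equal(codes, small_cohort.loc[ok, "stage"].to_numpy())

    def test_cart_monotone_and_lagged(self, small_cohort):
        for _, grp in small_cohort.sort_values("time").groupby("subject_id"):
            oc = grp["on_cart"].to_numpy()
            stage = grp["stage"].to_numpy()
            assert np.all(np.diff(oc) >= 0)
            fired = np.nonzero(stage >= 2)[0]
            if len(fired):
                k = fired[0]
                # initiation cannot precede the qualifying observation...
                assert oc[k] == 0
                assert np.all(oc[: k + 1] == 0)
                # ...and applies from the next visit onward
                assert np.all(oc[k + 1 :] == 1)
            else:
                assert np.all(oc == 0)
        assert (small_cohort.loc[small_cohort["on_cart"] == 1, "phase"] == "V").all()

    def test_non_monotone_npo_aborts_with_pattern(self):
        spec = ModelSpec(shared=("time",), npo=("log_vl_c",))
        params = ParamVector(
            thresholds=np.array([-1.0, 0.0, 1.0]),
            shared_coefs=np.zeros(1),
            category_coefs=np.array([[2.0, 0.0, -2.0]]),  # crossing logits
            re_cov=np.zeros((2, 2)),
        )
        cfg = SimConfig(n_subjects=30, seed=11)
        subs = simulate_subjects(cfg)
        visits = simulate_visits(subs, cfg)
        with pytest.raises(NonMonotoneError, match="covariates"):
            simulate_ordinal_outcomes(visits, params, spec, seed=12)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = SimConfig(n_subjects=15, seed=99)
        t1 = simulate_cohort(cfg)
        t2 = simulate_cohort(SimConfig(n_subjects=15, seed=99))
        pd.testing.assert_frame_equal(t1, t2)
        b1, b2 = io.StringIO(), io.StringIO()
        write_cohort(t1, b1)
        write_cohort(t2, b2)
        assert b1.getvalue() == b2.getvalue()

    def test_different_seed_differs(self):
        t1 = simulate_cohort(SimConfig(n_subjects=15, seed=99))
        t2 = simulate_cohort(SimConfig(n_subjects=15, seed=100))
        assert not t1.equals(t2)


class TestClinicalPanel:
    def test_noiseless_single_factor(self):
        lam = np.ones((3, 1))
        X, F = simulate_clinical_panel(lam, 200, noise_sd=0.0, seed=13, return_factors=True)
        for j in range(3):
            assert np.allclose(X[:, j], F[:, 0])

    def test_block_correlation_closed_form(self):
        lam = np.zeros((4, 2))
        lam[:2, 0] = 0.9
        lam[2:, 1] = 0.9
        noise = 0.5
        X = simulate_clinical_panel(lam, 20_000, noise_sd=noise, seed=14)
        r = np.corrcoef(X, rowvar=False)
        expected = 0.81 / (0.81 + noise**2)
        assert r[0, 1] == pytest.approx(expected, abs=0.02)
        assert abs(r[0, 2]) < 0.03

    def test_shape_validation(self):
        with pytest.raises(ValueError, match="more variables"):
            simulate_clinical_panel(np.ones((2, 3)), 100, 1.0, seed=0)
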