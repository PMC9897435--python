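"""Survival machinery vs hand computation and an independent implementation."""

import numpy as np
import pandas as pd
import pytest

from gagmced.simulate import generate_survival
from gagmced.survival import (
    build_design,
    concordance,
    cox_fit,
    cox_internal_validation,
    dichotomize_and_compare,
    km_estimate,
    logrank_test,
    median_followup,
    ph_check,
    rcs_basis,
    somers_dxy,
)


def _sim(n=300, beta=(0.5, -0.7), seed=1):
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    x2 = (rng.uniform(size=n) < 0.5).astype(float)
    lam = 0.05 * np.exp(beta[0] * x1 + beta[1] * x2)
    T = rng.exponential(1 / lam)
    C = rng.uniform(0, 40, n)
    return np.minimum(T, C), (T <= C).astype(int), np.column_stack([x1, x2])


class TestKM:
    def test_hand_computed_product_limit(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert km.median == 2.0

    def test_no_events_constant_one(self):
        km = km_estimate([5, 6, 7], [0, 0, 0])
        assert len(km.time) == 0 or np.all(km.survival == 1.0)

    def test_censoring_between_events(self):
        # events at 1 and 3, censoring at 2: S = 3/4, then 3/4 * 1/2
        km = km_estimate([1, 2, 3, 4], [1, 0, 1, 0])
        assert np.allclose(km.survival, [3 / 4, 3 / 8])

    def test_identical_groups_identical_curves(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 1]
        a, b = km_estimate(t, e), km_estimate(t, e)
        assert np.allclose(a.survival, b.survival)

    def test_reverse_km_median_followup(self):
        # all censored at 12: follow-up median is 12
        assert median_followup([12.0] * 5, [0] * 5) == 12.0


class TestLogrank:
    def test_hand_computed_two_group(self):
        """Textbook fixture: O-E table computed by hand.

        Group a: events at 1, 2; group b: event at 3.
        t=1: r=3(2a,1b), d=1(a): E_a=2/3, V=2/9
        t=2: r=2(1a,1b), d=1(a): E_a=1/2, V=1/4
        t=3: r=1(0a,1b), d=1(b): E_a=0,   V=0
        chi2 = (2 - 7/6)^2 / (2/9 + 1/4) = (5/6)^2 / (17/36)
        """
        res = logrank_test([1, 2, 3], [1, 1, 1], ["a", "a", "b"])
        assert res["chi2"] == pytest.approx((5 / 6) ** 2 / (17 / 36))

    def test_matches_cox_score_direction(self):
        t, e, X = _sim(seed=3)
        g = (X[:, 1] > 0).astype(int)
        res = logrank_test(t, e, g)
        assert 0.0 <= res["p"] <= 1.0

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], ["a", "a"])


class TestCox:
    def test_matches_established_implementation(self):
        from lifelines import CoxPHFitter

        t, e, X = _sim()
        fit = cox_fit(t, e, X, names=["x1", "x2"])
        df = pd.DataFrame({"t": t, "e": e, "x1": X[:, 0], "x2": X[:, 1]})
        cph = CoxPHFitter().fit(df, "t", "e")
        assert np.abs(fit.coef - cph.params_.to_numpy()).max() < 1e-4
        assert np.abs(fit.se - cph.standard_errors_.to_numpy()).max() < 1e-4

    def test_duplicated_data_same_coef_smaller_se(self):
        # duplication introduces ties, so Efron's correction moves the
        # estimate by O(1e-3); the theory check holds to that tolerance
        t, e, X = _sim(n=200, seed=5)
        f1 = cox_fit(t, e, X)
        f2 = cox_fit(np.r_[t, t], np.r_[e, e], np.vstack([X, X]))
        assert np.allclose(f1.coef, f2.coef, atol=1e-2)
        assert np.allclose(f2.se * np.sqrt(2), f1.se, rtol=0.05)

    def test_null_covariate_ci_covers_one(self):
        cover = 0
        for s in range(10):
            t, e, X = _sim(n=300, beta=(0.0, 0.0), seed=100 + s)
            f = cox_fit(t, e, X[:, :1])
            cover += f.ci_low[0] <= 1.0 <= f.ci_high[0]
        assert cover >= 8

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            cox_fit([1, 2], [0, 0], np.ones((2, 1)))


class TestDichotomize:
    def test_planted_hr_recovered_over_seeds(self):
        cover = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            scores = rng.normal(size=400)
            cutoff = np.quantile(scores, 0.5)
            low = scores <= cutoff
            surv = generate_survival(low, hr_low_vs_high=0.6, seed=500 + s)
            res = dichotomize_and_compare(
                scores, cutoff, surv["os_months"], surv["os_event"]
            )
            cover += res["ci_low"] <= 0.6 <= res["ci_high"]
        assert cover >= 18

    def test_single_stratum_errors(self):
        with pytest.raises(ValueError, match="single stratum"):
            dichotomize_and_compare(np.ones(50), 2.0, np.ones(50), np.ones(50, int))


class TestPHCheck:
    def test_proportional_data_usually_passes(self):
        ok = 0
        for s in range(10):
            t, e, X = _sim(n=300, seed=200 + s)
            fit = cox_fit(t, e, X)
            ok += ph_check(fit)["global_p"] > 0.01
        assert ok >= 9

    def test_time_varying_effect_detected(self):
        hits = 0
        for s in range(5):
            rng = np.random.default_rng(300 + s)
            n = 500
            x = (rng.uniform(size=n) < 0.5).astype(float)
            # different Weibull shapes: the hazard ratio crosses over time
            T = np.where(x > 0, 10 * rng.weibull(0.7, n), 10 * rng.weibull(1.8, n))
            C = rng.uniform(0, 30, n)
            t, e = np.minimum(T, C), (T <= C).astype(int)
            fit = cox_fit(t, e, x[:, None])
            hits += ph_check(fit)["global_p"] < 0.01
        assert hits >= 4

    def test_no_events_errors(self):
        t, e, X = _sim(n=50, seed=9)
        fit = cox_fit(t, e, X)
        fit.event = np.zeros_like(fit.event)
        with pytest.raises(ValueError):
            ph_check(fit)


class TestInternalValidation:
    def test_strong_signal_small_correction(self):
        t, e, X = _sim(n=500, beta=(1.0, -1.0), seed=11)
        design = type("D", (), {})()
        from gagmced.survival import SurvivalDesign

        design = SurvivalDesign(time=t, event=e, X=X, names=["x1", "x2"])
        res = cox_internal_validation(design, B=50, seed=1)
        assert res["correction_pct"] < 20.0

    def test_b_zero_errors(self):
        from gagmced.survival import SurvivalDesign

        design = SurvivalDesign(time=np.ones(10), event=np.ones(10, int), X=np.ones((10, 1)), names=["x"])
        with pytest.raises(ValueError):
            cox_internal_validation(design, B=0)


def test_concordance_small_example():
    # times 1,2,3 all events; score must rank earlier deaths higher
    assert concordance([1, 2, 3], [1, 1, 1], [3, 2, 1]) == 1.0
    assert concordance([1, 2, 3], [1, 1, 1], [1, 2, 3]) == 0.0
    assert somers_dxy([1, 2, 3], [1, 1, 1], [3, 2, 1]) == 1.0


def test_rcs_basis_shape_and_scaling():
    x = np.random.default_rng(0).uniform(20, 90, 300)
    b = rcs_basis(x)
    assert b.shape == (300, 2)
    assert np.allclose(b.mean(axis=0), 0, atol=1e-9)
    assert np.allclose(b.std(axis=0), 1, atol=1e-9)


def test_build_design_drops_missing_and_counts():
    df = pd.DataFrame(
        {
            "score": [1.0, 2.0, np.nan, 0.5],
            "os_months": [10.0, 20.0, 5.0, np.nan],
            "os_event": [1, 0, 1, 1],
            "age": [60.0, 70.0, 55.0, 65.0],
            "sex": ["M", "F", "M", "F"],
            "stage_group": ["S2", "S4/HG", "S1/LG", "S3"],
        }
    )
    d = build_design(df)
    assert d.n_dropped == 2
    assert d.X.shape[0] == 2
    assert "late_stage" in d.names
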