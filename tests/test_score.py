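"""Score construction: projection identities, size rule, cutoffs, round trips."""

import numpy as np
import pytest
from scipy.special import expit, logit

from gagmced.score import (
    ProjectedScoreModel,
    SelectionPath,
    TPrior,
    build_score,
    choose_size,
    fit_reference,
    project_submodel,
    prune_to_independent,
    set_cutoffs,
)


@pytest.fixture(scope="module")
def logistic_ref():
    rng = np.random.default_rng(0)
    n, k = 400, 6
    X = rng.standard_normal((n, k))
    beta = np.array([1.2, -1.0, 0, 0, 0, 0])
    y = (rng.uniform(size=n) < expit(X @ beta)).astype(int)
    return fit_reference(X, y, seed=1), X, y


class TestProjection:
    def test_identity_projection(self, logistic_ref):
        ref, X, y = logistic_ref
        proj = project_submodel(ref, list(range(X.shape[1])), n_clusters=None, thin_to=100)
        X1 = np.column_stack([np.ones(len(X)), X])
        idx = np.linspace(0, len(ref.draws) - 1, 100).round().astype(int)
        err = np.abs(proj.thetas @ X1.T - ref.draws[idx] @ X1.T).max()
        assert err < 1e-6

    def test_empty_subset_projects_to_mean_probability(self, logistic_ref):
        """Intercept-only KL minimizer matches logit of the mean fitted p."""
        ref, X, y = logistic_ref
        proj = project_submodel(ref, [], n_clusters=None, thin_to=50)
        X1 = np.column_stack([np.ones(len(X)), X])
        idx = np.linspace(0, len(ref.draws) - 1, 50).round().astype(int)
        p_mean = expit(ref.draws[idx] @ X1.T).mean(axis=1)
        assert np.allclose(proj.thetas[:, 0], logit(p_mean), atol=1e-6)

    def test_single_binary_feature_closed_form(self):
        """Projection onto one binary feature solves the two-cell logit."""
        rng = np.random.default_rng(3)
        n = 200
        x = (rng.uniform(size=n) < 0.5).astype(float)
        y = (rng.uniform(size=n) < expit(1.5 * x - 0.5)).astype(int)
        ref = fit_reference(x[:, None], y, seed=4)
        proj = project_submodel(ref, [0], n_clusters=None, thin_to=20)
        X1 = np.column_stack([np.ones(n), x])
        idx = np.linspace(0, len(ref.draws) - 1, 20).round().astype(int)
        for s in range(20):
            p = expit(ref.draws[idx[s]] @ X1.T)
            # weighted two-cell solution: q must equal the mean p in each cell
            t0, t1 = proj.thetas[s]
            assert expit(t0) == pytest.approx(p[x == 0].mean(), abs=1e-6)
            assert expit(t0 + t1) == pytest.approx(p[x == 1].mean(), abs=1e-6)


class TestSizeRule:
    def _path(self, diffs, ses):
        return SelectionPath(
            features=[f"f{i}" for i in range(len(diffs))],
            order=list(range(len(diffs))),
            elpd=[0.0] * len(diffs),
            elpd_diff=list(diffs),
            se_diff=list(ses),
            elpd_ref=0.0,
        )

    def test_rule_application(self):
        assert choose_size(self._path([-10, -3, -0.5], [2, 2, 1])) == 3

    def test_first_size_qualifies(self):
        assert choose_size(self._path([-0.5, -0.1], [1, 1])) == 1

    def test_fallback_to_cap_with_warning(self):
        p = self._path([-10, -8], [1, 1])
        assert choose_size(p) == 2
        assert p.warnings


class TestCutoffs:
    def test_counting_example(self):
        cuts = set_cutoffs(np.arange(1.0, 101.0), (0.95,))
        c = cuts["spec95"]["cutoff"]
        assert 95.0 <= c < 96.0
        assert np.sum(np.arange(1.0, 101.0) > c) == 5

    def test_all_equal_controls(self):
        cuts = set_cutoffs(np.full(50, 2.0), (0.95,))
        assert cuts["spec95"]["achieved_specificity"] == 1.0
        assert np.sum(np.full(50, 2.0) > cuts["spec95"]["cutoff"]) == 0

    def test_spec_one_gives_no_false_positives(self):
        s = np.random.default_rng(0).normal(size=200)
        cuts = set_cutoffs(s, (1.0,))
        assert np.sum(s > cuts["spec100"]["cutoff"]) == 0

    def test_cutoffs_monotone_in_specificity(self):
        s = np.random.default_rng(1).normal(size=500)
        cuts = set_cutoffs(s, (0.95, 0.99))
        assert cuts["spec99"]["cutoff"] >= cuts["spec95"]["cutoff"]

    def test_achieved_at_least_requested(self):
        s = np.random.default_rng(2).normal(size=137)
        for spec in (0.9, 0.95, 0.99):
            cuts = set_cutoffs(s, (spec,))
            key = f"spec{int(round(spec*100))}"
            assert cuts[key]["achieved_specificity"] >= spec


class TestReference:
    def test_null_covers_zero(self, rng):
        n, k = 400, 5
        X = rng.standard_normal((n, k))
        y = rng.permutation(np.r_[np.ones(n // 2), np.zeros(n // 2)]).astype(int)
        ref = fit_reference(X, y, seed=2)
        lo, hi = np.quantile(ref.draws[:, 1:], [0.025, 0.975], axis=0)
        covered = (lo <= 0) & (0 <= hi)
        assert covered.mean() >= 0.8

    def test_strong_effect_excluded_from_zero(self, rng):
        n = 600
        x = rng.standard_normal(n)
        y = (rng.uniform(size=n) < expit(2.0 * x)).astype(int)
        ref = fit_reference(x[:, None], y, seed=3)
        lo, hi = np.quantile(ref.draws[:, 1], [0.025, 0.975])
        assert lo > 0

    def test_rejects_missing_and_single_class(self):
        with pytest.raises(ValueError):
            fit_reference(np.array([[np.nan], [1.0]]), np.array([0, 1]))
        with pytest.raises(ValueError):
            fit_reference(np.zeros((5, 1)), np.zeros(5))


class TestScoreModel:
    def test_monotone_in_positive_feature(self, logistic_ref):
        ref, X, y = logistic_ref
        model, _ = build_score(X, y, [f"f{j}" for j in range(X.shape[1])], cap=3, seed=5)
        j = model.features.index("f0") if "f0" in model.features else None
        assert j is not None, "informative feature f0 should be selected"
        Xs = np.zeros((2, len(model.features)))
        Xs[1, j] = 1.0
        s = model.score(Xs)
        assert s[1] > s[0]

    def test_serialization_round_trip_bit_identical(self, logistic_ref):
        ref, X, y = logistic_ref
        model, _ = build_score(X, y, [f"f{j}" for j in range(X.shape[1])], cap=3, seed=6)
        clone = ProjectedScoreModel.from_json(model.to_json())
        Xs = np.random.default_rng(9).normal(size=(20, len(model.features)))
        assert np.array_equal(model.score(Xs), clone.score(Xs))

    def test_version_mismatch_rejected(self, logistic_ref):
        ref, X, y = logistic_ref
        model, _ = build_score(X, y, [f"f{j}" for j in range(X.shape[1])], cap=2, seed=7)
        bad = model.to_json().replace('"version": "1"', '"version": "0"')
        with pytest.raises(ValueError, match="version"):
            ProjectedScoreModel.from_json(bad)


class TestPrune:
    def test_keeps_only_concentrations(self):
        cand = ["plasma_cs_0s", "urine_frac_cs_0s", "urine_charge_cs", "urine_hs_ns", "plasma_ratio_4s_0s", "ha"]
        assert prune_to_independent(cand) == ["plasma_cs_0s", "urine_hs_ns", "ha"]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            prune_to_independent(["frac_cs_0s", "charge_cs"])
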