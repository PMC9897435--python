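"""Longitudinal mouse analysis: cage rule, PCA oracle, trend estimator."""

import numpy as np
import pandas as pd
import pytest

from gagmced.features import CONC_FEATURES
from gagmced.mouse import cage_filter, fit_trend, pca_timepoints, trend_table
from gagmced.simulate import GeneratorConfig, generate_mouse


class TestCageFilter:
    def test_all_alive_nothing_dropped(self):
        m = generate_mouse(seed=0)
        assert len(cage_filter(m.data)) == len(m.data)

    def test_dead_cagemate_drops_urine_row(self):
        m = generate_mouse(seed=0, dropout={"M01": 3})
        filtered = cage_filter(m.data)
        gone = filtered[
            (filtered["fluid"] == "urine")
            & (filtered["unit_id"] == "C01")
            & (filtered["timepoint"] == "metastasis")
        ]
        assert len(gone) == 0

    def test_plasma_rows_never_dropped_by_rule(self):
        m = generate_mouse(seed=0, dropout={"M01": 3})
        before = m.data[m.data["fluid"] == "plasma"]
        after = cage_filter(m.data)
        assert len(after[after["fluid"] == "plasma"]) == len(before)


class TestPCA:
    def test_loadings_match_eigendecomposition(self, rng):
        """2-feature toy with known covariance: PC1 along the dominant axis."""
        n = 400
        cov = np.array([[4.0, 1.2], [1.2, 1.0]])
        X = rng.multivariate_normal([0, 0], cov, size=n)
        df = pd.DataFrame(X, columns=["a", "b"])
        df["unit_id"] = "u"
        df["timepoint"] = "baseline"
        df["fluid"] = "plasma"
        res = pca_timepoints(df, ["a", "b"])
        # oracle: eigenvectors of the correlation matrix of the standardized data
        Z = (X - X.mean(0)) / X.std(0)
        vals, vecs = np.linalg.eigh(np.cov(Z.T))
        lead = vecs[:, np.argmax(vals)]
        got = np.polyfit(Z @ lead, res.coordinates["PC1"], 1)[0]
        assert abs(abs(got) - 1.0) < 1e-6

    def test_explained_variance_properties(self):
        m = generate_mouse(seed=1)
        res = pca_timepoints(m.data[m.data["fluid"] == "plasma"], CONC_FEATURES)
        assert res.explained_pct.sum() <= 100.0 + 1e-9
        assert np.all(np.diff(res.explained_pct) <= 1e-9)

    def test_invariant_to_feature_order(self):
        m = generate_mouse(seed=2)
        sub = m.data[m.data["fluid"] == "plasma"]
        a = pca_timepoints(sub, CONC_FEATURES)
        b = pca_timepoints(sub, CONC_FEATURES[::-1])
        assert np.allclose(np.abs(a.coordinates["PC1"]), np.abs(b.coordinates["PC1"]), atol=1e-8)

    def test_null_centroids_overlap(self):
        cfg = GeneratorConfig(
            mouse_plasma_multipliers=[1, 1, 1, 1], mouse_urine_multipliers=[1, 1, 1, 1]
        )
        m = generate_mouse(cfg, seed=3)
        res = pca_timepoints(m.data[m.data["fluid"] == "plasma"], CONC_FEATURES)
        cent = res.coordinates.groupby("timepoint")[["PC1", "PC2"]].mean()
        spread = res.coordinates[["PC1", "PC2"]].std()
        dist = np.linalg.norm(cent.max() - cent.min())
        assert dist < 2.0 * np.linalg.norm(spread)


class TestTrend:
    def test_zero_trend_covers_zero(self):
        cfg = GeneratorConfig(
            mouse_plasma_multipliers=[1, 1, 1, 1], mouse_urine_multipliers=[1, 1, 1, 1]
        )
        covered = 0
        for s in range(10):
            m = generate_mouse(cfg, seed=s)
            res = trend_table(m.data, ["cs_0s"], "plasma", seed=s)
            row = res[res["timepoint"] == "metastasis"].iloc[0]
            covered += row["cri_low"] <= 0.0 <= row["cri_high"]
        assert covered >= 9

    def test_exact_zero_when_levels_identical(self):
        """If every timepoint repeats the baseline values, the point estimate
        of percent change is numerically zero."""
        units = [f"u{i}" for i in range(8)]
        base = np.linspace(1.0, 2.0, 8)
        rows = []
        for tp in ("baseline", "localized", "postop", "metastasis"):
            for u, v in zip(units, base):
                rows.append({"unit_id": u, "timepoint": tp, "fluid": "plasma", "f": v})
        res = fit_trend(pd.DataFrame(rows), "f", seed=0)
        assert np.abs(res["pct_change"]).max() < 1.0

    def test_single_unit_errors(self):
        df = pd.DataFrame(
            {
                "unit_id": ["u1"] * 4,
                "timepoint": ["baseline", "localized", "postop", "metastasis"],
                "fluid": ["plasma"] * 4,
                "f": [1.0, 2.0, 3.0, 4.0],
            }
        )
        with pytest.raises(ValueError):
            fit_trend(df, "f")

    def test_random_effect_shrinkage(self):
        """Unit-level posterior means lie between unit residual means and 0."""
        from gagmced._samplers import gibbs_lmm

        rng = np.random.default_rng(4)
        n_units, per = 10, 8
        b_true = rng.normal(0, 1.0, n_units)
        g = np.repeat(np.arange(n_units), per)
        y = b_true[g] + rng.normal(0, 1.0, n_units * per)
        draws = gibbs_lmm(y, np.ones((len(y), 1)), g, seed=1)
        bhat = draws["b"].mean(axis=0)
        resid_means = np.array([y[g == j].mean() for j in range(n_units)]) - draws["beta"][:, 0].mean()
        frac = bhat / np.where(resid_means == 0, 1, resid_means)
        assert np.all(frac > 0.2) and np.all(frac < 1.05)
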