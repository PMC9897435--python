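"""Feature calculus: derived features, detectability, standardization, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gagmced import features as ft


def make_panel(cs=None, hs=None, ha=0.0, fluid="plasma"):
    return ft.DisaccharidePanel(fluid, cs=cs or {}, hs=hs or {}, ha=ha)


class TestComputeFeatures:
    @pytest.mark.parametrize(
        "cs, expect",
        [
            # unsulfated-only: zero charge, 100% 0S fraction
            ({"0s": 2.0}, {"total_cs": 2.0, "frac_cs_0s": 100.0, "charge_cs": 0.0, "ratio_4s_0s": 0.0}),
            # hand arithmetic: 50/50 split of 0S and mono-sulfated 4S
            ({"0s": 1.0, "4s": 1.0}, {"total_cs": 2.0, "frac_cs_0s": 50.0, "frac_cs_4s": 50.0, "charge_cs": 0.5, "ratio_4s_0s": 1.0}),
            # maximal sulfation bound
            ({"tris": 5.0}, {"charge_cs": 3.0}),
        ],
    )
    def test_worked_examples(self, cs, expect):
        v = ft.compute_features(make_panel(cs=cs))
        for k, val in expect.items():
            assert v[k] == pytest.approx(val)

    def test_feature_count_is_39(self):
        v = ft.compute_features(make_panel(cs={"0s": 1.0}))
        assert len(ft.ALL_FEATURES) == 39
        assert all(f in v.index for f in ft.ALL_FEATURES)

    def test_zero_denominator_ratio_is_missing(self):
        v = ft.compute_features(make_panel(cs={"4s": 1.0}))
        assert np.isnan(v["ratio_4s_0s"])

    def test_negative_concentration_rejected(self):
        with pytest.raises(ft.ValidationError):
            make_panel(cs={"0s": -1.0})

    def test_unknown_species_rejected(self):
        with pytest.raises(ft.ValidationError):
            make_panel(cs={"9s": 1.0})

    @settings(max_examples=50, deadline=None)
    @given(
        vals=st.lists(st.floats(0.0, 50.0), min_size=17, max_size=17),
        c=st.floats(0.1, 100.0),
    )
    def test_scale_invariance(self, vals, c):
        """Fractions, charges and ratios are invariant to global rescaling."""
        row = pd.DataFrame([dict(zip(ft.CONC_FEATURES, vals))])
        a = ft.add_derived_features(row).iloc[0]
        b = ft.add_derived_features(row * c).iloc[0]
        rel = [f for f in ft.DERIVED_FEATURES if not f.startswith("total")]
        for f in rel:
            if np.isnan(a[f]):
                assert np.isnan(b[f])
            else:
                assert b[f] == pytest.approx(a[f], rel=1e-9, abs=1e-9)
        assert 0.0 <= a["charge_cs"] <= 3.0
        assert 0.0 <= a["charge_hs"] <= 3.0
        for cls in ("cs", "hs"):
            tot = a[f"total_{cls}"]
            if tot > 0:
                fr = sum(a[f"frac_{cls}_{s}"] for s in (ft.CS_SPECIES if cls == "cs" else ft.HS_SPECIES))
                assert fr == pytest.approx(100.0, abs=1e-9)


class TestDetectability:
    def test_below_threshold_everywhere(self):
        df = pd.DataFrame({c: [0.05] * 4 for c in ft.CONC_FEATURES})
        df["fluid"] = "plasma"
        mask = ft.detectability_filter(df)
        assert mask["plasma"] == []

    def test_median_rule(self):
        df = pd.DataFrame({c: [0.0] * 3 for c in ft.CONC_FEATURES})
        df["cs_0s"] = [0.05, 0.15, 0.25]  # median 0.15 > 0.1
        df["fluid"] = "urine"
        mask = ft.detectability_filter(df)
        assert "cs_0s" in mask["urine"]

    def test_sparse_plasma_rich_urine_pattern_on_default_cohort(self, dev_features):
        mask = ft.detectability_filter(dev_features)
        assert len(mask["plasma"]) == 6
        assert len(mask["urine"]) == 17
        # plasma: the two concentrations plus their dependent features only
        assert set(mask["plasma"]) == {
            "cs_0s", "cs_4s", "total_cs", "frac_cs_0s", "frac_cs_4s", "ratio_4s_0s",
        }
        # charge needs >= 2 sulfated detectable species: present in urine CS only
        assert "charge_cs" in mask["urine"] and "charge_hs" not in mask["urine"]
        assert "charge_cs" not in mask["plasma"]

    def test_empty_cohort_errors(self):
        with pytest.raises(ft.ValidationError):
            ft.detectability_filter(pd.DataFrame())


class TestStandardize:
    def test_closed_form_z(self):
        df = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        z, _ = ft.standardize(df, ["f"])
        assert np.allclose(z["f"], [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_stored_transform_is_idempotent(self):
        df = pd.DataFrame({"f": [1.0, 5.0, 9.0, 2.0]})
        z, tr = ft.standardize(df, ["f"])
        assert np.allclose(tr.transform(df)["f"], z["f"])

    def test_shift_invariance(self):
        df = pd.DataFrame({"f": [1.0, 2.0, 5.0]})
        z1, _ = ft.standardize(df, ["f"])
        z2, _ = ft.standardize(df + 10.0, ["f"])
        assert np.allclose(z1["f"], z2["f"])

    def test_zero_variance_names_feature(self):
        df = pd.DataFrame({"bad": [1.0, 1.0, 1.0]})
        with pytest.raises(ft.ValidationError, match="bad"):
            ft.standardize(df, ["bad"])


class TestOutlierScreen:
    def test_homogeneous_cohort_no_flags(self):
        df = pd.DataFrame({c: [1.0] * 20 for c in ft.CONC_FEATURES})
        flags = ft.outlier_screen(df)
        assert flags.sum() == 0

    def test_extreme_total_cs_flagged(self, rng):
        df = pd.DataFrame({c: rng.normal(1.0, 0.05, 20).clip(0) for c in ft.CONC_FEATURES})
        df.loc[0, "cs_0s"] = 100 * 8
        flags = ft.outlier_screen(df)
        assert flags.iloc[0]

    def test_planted_contamination_mostly_caught(self, rng):
        n = 500
        df = pd.DataFrame({c: rng.normal(1.0, 0.1, n).clip(0) for c in ft.CONC_FEATURES})
        bad = rng.choice(n, size=10, replace=False)
        df.loc[bad, "cs_0s"] += 10 * 0.1 * 10  # 10 SD away, well outside the fence
        flags = ft.outlier_screen(df, features=["cs_0s"])
        assert flags.iloc[bad].mean() >= 0.95

    def test_too_few_samples(self):
        df = pd.DataFrame({c: [1.0] * 5 for c in ft.CONC_FEATURES})
        with pytest.raises(ft.ValidationError):
            ft.outlier_screen(df)


def test_combine_fluids_joins_on_subject(small_cohort):
    from gagmced.features import add_derived_features, combine_fluids, detectability_filter

    df = add_derived_features(small_cohort.data)
    mask = detectability_filter(df)
    wide = combine_fluids(df, mask)
    assert len(wide) == df["subject_id"].nunique()
    assert "plasma_cs_0s" in wide.columns and "urine_cs_0s" in wide.columns
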