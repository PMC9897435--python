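"""Stage-chaining helpers: from a raw cohort table to a training matrix.

These are the same steps the command-line interface runs: derived-feature
calculus, detectability filtering, per-fluid or combined wide tables,
standardization, and the binary any-cancer response.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import features as ft


def training_matrix(
    cohort: pd.DataFrame, fluid: str, screen_outliers: bool = False
) -> tuple[np.ndarray, np.ndarray, list, ft.Standardizer, pd.DataFrame]:
    """Build (X, y, feature names, standardizer, sample table) for a fluid.

    ``fluid`` is ``plasma``, ``urine`` or ``combined`` (subjects with both
    fluids, columns prefixed by fluid). Features are the detectable set with
    finite values and non-zero variance; X is standardized to mean 0 / SD 1.
    """
    df = ft.add_derived_features(cohort) if "total_cs" not in cohort.columns else cohort
    mask = ft.detectability_filter(df)
    if screen_outliers:
        drop = pd.Series(False, index=df.index)
        for fl, sub in df.groupby("fluid"):
            if len(sub) >= 10:
                drop.loc[sub.index] = ft.outlier_screen(sub, mask[fl])
        df = df[~drop]
    if fluid == "combined":
        d = ft.combine_fluids(df, mask)
        feats = [f"{fl}_{f}" for fl in ("plasma", "urine") for f in mask.get(fl, [])]
    else:
        d = df[df["fluid"] == fluid].reset_index(drop=True)
        feats = mask[fluid]
    feats = [f for f in feats if f in d and d[f].notna().all() and d[f].std() > 0]
    std, tr = ft.standardize(d, feats)
    y = (d["diagnosis"] == "cancer").astype(int).to_numpy()
    return std[feats].to_numpy(float), y, feats, tr, d
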