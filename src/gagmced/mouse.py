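"""Longitudinal free-GAGome trend analysis across tumor-progression
timepoints (baseline, localized growth, post-operative resection,
metastasis).

Plasma is measured per mouse, urine as 24-h pooled collections per
two-mouse metabolic cage; pooled urine samples are only usable when both
cage mates were alive at the timepoint. Trends are estimated per feature
with a Bayesian normal mixed model (timepoint fixed effect, unit random
intercept, conjugate Gibbs sampling) on the standardized scale and reported
as percent change vs baseline after back-transforming the fitted levels to
the raw concentration scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from ._samplers import gibbs_lmm
from .simulate import TIMEPOINTS


def cage_filter(table: pd.DataFrame) -> pd.DataFrame:
    """Drop pooled-urine rows where not both cage mates were alive.

    Plasma rows are never dropped by this rule.
    """
    if "alive_pair" not in table.columns:
        return table
    keep = (table["fluid"] != "urine") | table["alive_pair"].fillna(False)
    return table[keep].reset_index(drop=True)


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # unit_id, timepoint, PC1, PC2
    explained_pct: np.ndarray
    ellipses: pd.DataFrame  # per-timepoint bivariate-t 95% ellipse parameters


def _bivariate_t_ellipse(points: np.ndarray, level: float = 0.95) -> dict:
    """95% coverage ellipse of a bivariate t fitted by moments.

    df is fixed at max(n-2, 3); the ellipse radius along each principal axis
    is sqrt(2 F_{2,df}(level)) times the axis SD, the classical confidence
    ellipse for a t-distributed cloud.
    """
    n = len(points)
    df = max(n - 2, 3)
    center = points.mean(axis=0)
    cov = np.cov(points.T) if n > 1 else np.eye(2)
    vals, vecs = np.linalg.eigh(cov)
    r = np.sqrt(2.0 * stats.f.ppf(level, 2, df))
    angle = float(np.degrees(np.arctan2(vecs[1, 1], vecs[0, 1])))
    return {
        "cx": float(center[0]),
        "cy": float(center[1]),
        "width": float(2 * r * np.sqrt(max(vals[1], 0))),
        "height": float(2 * r * np.sqrt(max(vals[0], 0))),
        "angle_deg": angle,
        "df": df,
        "n": n,
    }


def pca_timepoints(
    table: pd.DataFrame, features: list[str], n_components: int = 2
) -> PCAResult:
    """PCA of centered/scaled features, labelled by progression timepoint."""
    df = table.dropna(subset=features)
    X = df[features].to_numpy(float)
    sd = X.std(axis=0)
    keep = sd > 0
    Xz = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=n_components, random_state=0)
    coords = pca.fit_transform(Xz)
    out = df[["unit_id", "timepoint", "fluid"]].copy()
    for c in range(n_components):
        out[f"PC{c+1}"] = coords[:, c]
    ell = []
    for tp in TIMEPOINTS:
        pts = coords[(df["timepoint"] == tp).to_numpy(), :2]
        if len(pts) >= 3:
            ell.append({"timepoint": tp, **_bivariate_t_ellipse(pts)})
    return PCAResult(
        coordinates=out.reset_index(drop=True),
        explained_pct=100.0 * pca.explained_variance_ratio_,
        ellipses=pd.DataFrame(ell),
    )


def fit_trend(
    table: pd.DataFrame,
    feature: str,
    seed: int = 0,
    n_draws: int = 2000,
    cri_level: float = 0.95,
) -> pd.DataFrame:
    """Percent change vs baseline per timepoint with credible intervals.

    The feature is standardized, modelled as standardized level ~ timepoint
    (fixed) + unit (random intercept) by Gibbs sampling, and fitted levels
    are back-transformed to the raw scale before forming
    100*(level_t - level_baseline)/level_baseline per posterior draw. If the
    baseline raw-scale level of a draw is <= 0 the percent change is
    undefined and that draw is dropped (fraction reported).
    """
    df = table.dropna(subset=[feature]).copy()
    units = df["unit_id"].unique()
    if len(units) < 2:
        raise ValueError("need >= 2 units")
    tps = [t for t in TIMEPOINTS if t in set(df["timepoint"])]
    if len(tps) < 2:
        raise ValueError("need >= 2 timepoints")
    y_raw = df[feature].to_numpy(float)
    mu, sd = y_raw.mean(), y_raw.std()
    if sd == 0:
        raise ValueError(f"constant feature {feature}")
    y = (y_raw - mu) / sd
    X = np.column_stack(
        [np.ones(len(df))]
        + [(df["timepoint"] == tp).to_numpy(float) for tp in tps[1:]]
    )
    draws = gibbs_lmm(y, X, df["unit_id"].to_numpy(), seed=seed, n_draws=n_draws)
    beta = draws["beta"]  # (S, 1 + len(tps)-1)
    base_raw = mu + sd * beta[:, 0]
    ok = base_raw > 0
    rows = []
    a = (1.0 - cri_level) / 2.0
    for i, tp in enumerate(tps[1:], start=1):
        level_raw = mu + sd * (beta[:, 0] + beta[:, i])
        pct = 100.0 * (level_raw[ok] - base_raw[ok]) / base_raw[ok]
        if len(pct) < 100:
            rows.append(
                {"feature": feature, "timepoint": tp, "pct_change": np.nan,
                 "cri_low": np.nan, "cri_high": np.nan, "frac_defined": float(ok.mean())}
            )
            continue
        lo, hi = np.quantile(pct, [a, 1.0 - a])
        rows.append(
            {
                "feature": feature,
                "timepoint": tp,
                "pct_change": float(np.median(pct)),
                "cri_low": float(lo),
                "cri_high": float(hi),
                "frac_defined": float(ok.mean()),
            }
        )
    return pd.DataFrame(rows)


def trend_table(
    table: pd.DataFrame,
    features: list[str],
    fluid: str,
    seed: int = 0,
    n_draws: int = 2000,
) -> pd.DataFrame:
    """Run :func:`fit_trend` per feature on one fluid after cage filtering."""
    sub = cage_filter(table)
    sub = sub[sub["fluid"] == fluid]
    rng = np.random.default_rng(seed)
    out = []
    for feat in features:
        if sub[feat].std() == 0:
            continue
        out.append(fit_trend(sub, feat, seed=int(rng.integers(2**31 - 1)), n_draws=n_draws))
    return pd.concat(out, ignore_index=True)
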