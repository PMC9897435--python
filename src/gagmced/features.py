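"""GAGome feature calculus.

The free GAGome of a biofluid sample is the concentration profile of 17
glycosaminoglycan disaccharides — eight chondroitin-sulfate (CS) species,
eight heparan-sulfate (HS) species, and hyaluronic acid (HA) — measured in
ug/mL. From these, 22 features are derived: class totals, dimensionless
sulfation charges, two CS ratios, and 16 mass fractions (%w/w), for 39
features per fluid. This module turns raw panels into the full feature set
and applies the detectability, standardization, and outlier screens used
before any modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CS_SPECIES = ["0s", "2s", "6s", "4s", "2s6s", "2s4s", "4s6s", "tris"]
HS_SPECIES = ["0s", "2s", "6s", "ns", "ns6s", "ns2s", "2s6s", "tris"]

CS_CONC = [f"cs_{s}" for s in CS_SPECIES]
HS_CONC = [f"hs_{s}" for s in HS_SPECIES]
CONC_FEATURES = CS_CONC + HS_CONC + ["ha"]

#: sulfo-group count per disaccharide species (0S carries none, TriS three)
SULFO_WEIGHTS = {
    "0s": 0,
    "2s": 1,
    "6s": 1,
    "4s": 1,
    "ns": 1,
    "2s6s": 2,
    "2s4s": 2,
    "4s6s": 2,
    "ns6s": 2,
    "ns2s": 2,
    "tris": 3,
}

FRAC_CS = [f"frac_cs_{s}" for s in CS_SPECIES]
FRAC_HS = [f"frac_hs_{s}" for s in HS_SPECIES]
DERIVED_FEATURES = (
    ["total_cs", "total_hs", "charge_cs", "charge_hs", "ratio_4s_0s", "ratio_6s_0s"]
    + FRAC_CS
    + FRAC_HS
)
ALL_FEATURES = CONC_FEATURES + DERIVED_FEATURES
RATIO_FEATURES = ["ratio_4s_0s", "ratio_6s_0s"]

FLUIDS = ("plasma", "urine")

METADATA_COLUMNS = [
    "sample_id",
    "subject_id",
    "fluid",
    "batch",
    "diagnosis",
    "cancer_type",
    "stage_group",
    "age",
    "sex",
    "os_months",
    "os_event",
    "crp_mg_dl",
    "hdl_mmol_l",
]


class ValidationError(ValueError):
    """Raised when an input panel or cohort violates the schema."""


@dataclass
class DisaccharidePanel:
    """One sample's 17 raw disaccharide concentrations (ug/mL) for one fluid.

    Below-LOD measurements should be entered as 0.0 (the assay reports
    semi-absolute concentrations and undetectable features are dropped
    downstream, so zero-imputation does not distort any retained feature).
    """

    fluid: str
    cs: dict = field(default_factory=dict)
    hs: dict = field(default_factory=dict)
    ha: float = 0.0

    def __post_init__(self):
        if self.fluid not in FLUIDS:
            raise ValidationError(f"unknown fluid {self.fluid!r}")
        for name, mapping, species in (("cs", self.cs, CS_SPECIES), ("hs", self.hs, HS_SPECIES)):
            unknown = set(mapping) - set(species)
            if unknown:
                raise ValidationError(f"unknown {name.upper()} species {sorted(unknown)}")
            for k, v in mapping.items():
                if not np.isfinite(v) or v < 0:
                    raise ValidationError(f"{name}_{k} concentration must be >= 0, got {v}")
        if not np.isfinite(self.ha) or self.ha < 0:
            raise ValidationError(f"ha concentration must be >= 0, got {self.ha}")

    def as_series(self) -> pd.Series:
        vals = {f"cs_{s}": float(self.cs.get(s, 0.0)) for s in CS_SPECIES}
        vals.update({f"hs_{s}": float(self.hs.get(s, 0.0)) for s in HS_SPECIES})
        vals["ha"] = float(self.ha)
        return pd.Series(vals)


def compute_features(panel: DisaccharidePanel) -> pd.Series:
    """Compute the 39-feature GAGome vector for a single panel.

    Totals are sums of the class concentrations; mass fractions are
    percentages of the class total (0 when the total is 0); the charge is the
    fraction-weighted mean sulfo-group count, hence dimensionless in [0, 3];
    ratios with a zero denominator are missing (NaN), not infinite.
    """
    row = panel.as_series()
    return add_derived_features(row.to_frame().T).iloc[0]


def add_derived_features(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized derived-feature calculus over a concentration table.

    ``df`` must contain the 17 concentration columns; the 22 derived columns
    are (re)computed and appended. Negative concentrations are rejected.
    """
    missing = [c for c in CONC_FEATURES if c not in df.columns]
    if missing:
        raise ValidationError(f"missing concentration columns: {missing}")
    conc = df[CONC_FEATURES].astype(float)
    if (conc.to_numpy() < 0).any():
        bad = conc.columns[(conc < 0).any(axis=0)].tolist()
        raise ValidationError(f"negative concentrations in columns {bad}")

    out = df.copy()
    total_cs = conc[CS_CONC].sum(axis=1)
    total_hs = conc[HS_CONC].sum(axis=1)
    out["total_cs"] = total_cs
    out["total_hs"] = total_hs

    with np.errstate(divide="ignore", invalid="ignore"):
        for s in CS_SPECIES:
            frac = 100.0 * conc[f"cs_{s}"] / total_cs
            out[f"frac_cs_{s}"] = frac.where(total_cs > 0, 0.0)
        for s in HS_SPECIES:
            frac = 100.0 * conc[f"hs_{s}"] / total_hs
            out[f"frac_hs_{s}"] = frac.where(total_hs > 0, 0.0)
        out["ratio_4s_0s"] = (conc["cs_4s"] / conc["cs_0s"]).where(conc["cs_0s"] > 0, np.nan)
        out["ratio_6s_0s"] = (conc["cs_6s"] / conc["cs_0s"]).where(conc["cs_0s"] > 0, np.nan)

    charge_cs = sum(SULFO_WEIGHTS[s] * out[f"frac_cs_{s}"] for s in CS_SPECIES) / 100.0
    charge_hs = sum(SULFO_WEIGHTS[s] * out[f"frac_hs_{s}"] for s in HS_SPECIES) / 100.0
    out["charge_cs"] = charge_cs
    out["charge_hs"] = charge_hs
    return out


def _dependent_feature_mask(detectable_conc: set[str]) -> list[str]:
    """Derived features retained for a set of detectable concentrations.

    Totals are kept when the class has at least one detectable species;
    a mass fraction is kept iff its species is detectable; a ratio needs both
    constituents; a charge needs at least two detectable *sulfated* species of
    its class (with a single one it is a deterministic rescaling of that
    species' fraction and carries no information).
    """
    kept: list[str] = []
    det_cs = [s for s in CS_SPECIES if f"cs_{s}" in detectable_conc]
    det_hs = [s for s in HS_SPECIES if f"hs_{s}" in detectable_conc]
    if det_cs:
        kept.append("total_cs")
    if det_hs:
        kept.append("total_hs")
    kept += [f"frac_cs_{s}" for s in det_cs]
    kept += [f"frac_hs_{s}" for s in det_hs]
    if "cs_4s" in detectable_conc and "cs_0s" in detectable_conc:
        kept.append("ratio_4s_0s")
    if "cs_6s" in detectable_conc and "cs_0s" in detectable_conc:
        kept.append("ratio_6s_0s")
    if sum(1 for s in det_cs if SULFO_WEIGHTS[s] > 0) >= 2:
        kept.append("charge_cs")
    if sum(1 for s in det_hs if SULFO_WEIGHTS[s] > 0) >= 2:
        kept.append("charge_hs")
    return kept


def detectability_filter(
    cohort: pd.DataFrame, threshold: float = 0.1
) -> dict[str, list[str]]:
    """Per-fluid list of detectable GAGome features.

    A concentration feature is detectable in a fluid iff its median across
    that fluid's samples exceeds ``threshold`` (ug/mL); derived features
    follow from the detectable concentration set (see
    :func:`_dependent_feature_mask`). Returns ``{fluid: [feature, ...]}`` in
    canonical feature order.
    """
    if cohort is None or len(cohort) == 0:
        raise ValidationError("empty cohort")
    result: dict[str, list[str]] = {}
    for fluid, sub in cohort.groupby("fluid", sort=False):
        medians = sub[CONC_FEATURES].median(axis=0)
        detectable = {c for c in CONC_FEATURES if medians[c] > threshold}
        kept = [c for c in CONC_FEATURES if c in detectable]
        kept += _dependent_feature_mask(detectable)
        result[fluid] = [f for f in ALL_FEATURES if f in kept]
    return result


@dataclass
class Standardizer:
    """Center/scale transform fitted on training data and reusable on new data.

    Uses the population SD convention (ddof=0). Raises on zero-variance
    features, naming the offender.
    """

    features: list[str] = field(default_factory=list)
    mean_: dict = field(default_factory=dict)
    sd_: dict = field(default_factory=dict)

    def fit(self, df: pd.DataFrame, features: list[str]) -> "Standardizer":
        self.features = list(features)
        for f in self.features:
            x = df[f].to_numpy(dtype=float)
            x = x[np.isfinite(x)]
            mu, sd = float(np.mean(x)), float(np.std(x))
            if sd == 0.0:
                raise ValidationError(f"zero-variance feature: {f}")
            self.mean_[f] = mu
            self.sd_[f] = sd
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for f in self.features:
            out[f] = (df[f].astype(float) - self.mean_[f]) / self.sd_[f]
        return out

    def fit_transform(self, df: pd.DataFrame, features: list[str]) -> pd.DataFrame:
        return self.fit(df, features).transform(df)

    def to_dict(self) -> dict:
        return {"features": self.features, "mean": self.mean_, "sd": self.sd_}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(features=list(d["features"]), mean_=dict(d["mean"]), sd_=dict(d["sd"]))


def standardize(
    cohort: pd.DataFrame, features: list[str]
) -> tuple[pd.DataFrame, Standardizer]:
    """Standardize selected features to mean 0 / SD 1; returns the transform."""
    tr = Standardizer()
    return tr.fit_transform(cohort, features), tr


_MAD_SCALE = 1.4826  # consistency constant: MAD*1.4826 estimates sigma for normal data


def outlier_screen(
    cohort: pd.DataFrame,
    features: list[str] | None = None,
    k_mad: float = 5.0,
) -> pd.Series:
    """Two-step robust outlier screen; returns a boolean flag per row.

    Step 1 flags samples whose total CS lies outside median +/- k*MAD
    (normalized MAD); step 2 applies the same rule to every feature in
    ``features`` (typically the detectable set). If a feature's MAD is 0 the
    screen falls back to a 1.5*IQR fence for that feature.
    """
    if len(cohort) < 10:
        raise ValidationError("outlier screen needs >= 10 samples per fluid")
    df = cohort
    if "total_cs" not in df.columns:
        df = add_derived_features(df)
    screen_cols = ["total_cs"] + [f for f in (features or []) if f != "total_cs"]
    flags = pd.Series(False, index=df.index)
    for col in screen_cols:
        x = df[col].to_numpy(dtype=float)
        finite = np.isfinite(x)
        med = np.nanmedian(x[finite])
        mad = _MAD_SCALE * np.nanmedian(np.abs(x[finite] - med))
        if mad > 0:
            lo, hi = med - k_mad * mad, med + k_mad * mad
        else:
            q1, q3 = np.nanpercentile(x[finite], [25, 75])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        with np.errstate(invalid="ignore"):
            flags |= pd.Series((x < lo) | (x > hi), index=df.index).fillna(False)
    return flags


def combine_fluids(cohort: pd.DataFrame, features_by_fluid: dict[str, list[str]]) -> pd.DataFrame:
    """Join a subject's plasma and urine features into one wide row.

    Only subjects with both fluids available are retained; feature columns
    are prefixed ``plasma_`` / ``urine_``. Metadata is taken from the plasma
    row.
    """
    pieces = {}
    for fluid in FLUIDS:
        sub = cohort[cohort["fluid"] == fluid]
        feats = features_by_fluid.get(fluid, [])
        piece = sub.set_index("subject_id")[feats].rename(
            columns={f: f"{fluid}_{f}" for f in feats}
        )
        meta_cols = [
            c
            for c in METADATA_COLUMNS
            if c in sub.columns and c not in ("sample_id", "fluid", "subject_id")
        ]
        pieces[fluid] = (piece, sub.set_index("subject_id")[meta_cols])
    common = pieces["plasma"][0].index.intersection(pieces["urine"][0].index)
    out = pd.concat(
        [pieces["plasma"][1].loc[common], pieces["plasma"][0].loc[common], pieces["urine"][0].loc[common]],
        axis=1,
    )
    return out.reset_index()
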