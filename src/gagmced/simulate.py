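"""Synthetic GAGome cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: per-feature skew-normal concentrations with cancer-type fixed
effects and batch random effects on the location, multiplicative
type-by-batch variance structure, truncation at zero and censoring below the
0.1 ug/mL limit of detection (calibrated so that 6 plasma and 17 urine
features are detectable), weakly stage-dependent stage labels, CRP/HDL-C
confounder shifts, Weibull/exponential survival tied to a score group, and
4-timepoint mouse plasma/urine trajectories.

Only the 17 raw concentrations are generated; every derived feature must be
computed by :mod:`gagmced.features`, so the feature calculus is exercised on
all synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .features import CONC_FEATURES, add_derived_features

TIMEPOINTS = ["baseline", "localized", "postop", "metastasis"]

# median concentrations (ug/mL) chosen to reproduce the detectability
# pattern of real biofluids: in plasma only 0S and 4S CS exceed the LOD; in
# urine four CS species plus 0S and NS HS do.
_PLASMA_MEDIANS = {"cs_0s": 1.6, "cs_4s": 0.35}
_URINE_MEDIANS = {
    "cs_0s": 3.0,
    "cs_4s": 2.0,
    "cs_6s": 1.5,
    "cs_2s6s": 0.30,
    "hs_0s": 1.5,
    "hs_ns": 0.5,
}
_TRACE_MEDIAN = 0.02  # undetectable species sit well below the 0.1 ug/mL LOD

DEFAULT_CANCER_TYPES = ["BC", "CRC", "NHL", "PCa", "RCC"]

# effect template (location shifts in SD units of the feature):
# 0S CS rises in every cancer type in both fluids; plasma 4S CS falls in
# CRC and NHL (lowering the plasma CS charge); urine 2S6S CS rises in PCa;
# urine 0S HS rises in RCC.
def _default_effects(types: list[str]) -> dict:
    eff: dict = {t: {"plasma": {}, "urine": {}} for t in types}
    for t in types:
        eff[t]["plasma"]["cs_0s"] = 0.8
        eff[t]["urine"]["cs_0s"] = 0.8
    for t in ("CRC", "NHL"):
        if t in eff:
            eff[t]["plasma"]["cs_4s"] = -0.6
    if "PCa" in eff:
        eff["PCa"]["urine"]["cs_2s6s"] = 0.8
    if "RCC" in eff:
        eff["RCC"]["urine"]["hs_0s"] = 0.5
    return eff


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-cohort generator.

    Locations are parameterized by target medians (ug/mL); ``cv`` sets the
    skew-normal scale as a fraction of the median; ``alpha`` is the
    skew-normal shape shared across features. Effects are location shifts in
    SD (omega) units per (cancer type, fluid, feature). ``batch_sd`` is the
    SD of additive batch effects in omega units; ``variance_multipliers``
    optionally scales omega per (type, batch).
    """

    n_healthy: int = 300
    n_per_cancer_type: int = 40
    cancer_types: list = field(default_factory=lambda: list(DEFAULT_CANCER_TYPES))
    cv: float = 0.30
    alpha: float = 3.0
    effects: dict | None = None
    n_batches: int = 4
    batch_sd: float = 0.15
    variance_multipliers: dict | None = None
    lod: float = 0.1
    stage_slope: float = 0.4
    crp_effect: float = 0.33
    hdl_effect: float = -0.17
    hr_low_vs_high: float = 0.61
    event_fraction: float = 0.5
    baseline_hazard: float = 0.03
    weibull_shape: float = 1.0
    mouse_plasma_multipliers: list = field(
        default_factory=lambda: [1.0, 1.5, 1.8, 2.48]
    )
    mouse_urine_multipliers: list = field(
        default_factory=lambda: [1.0, 1.3, 1.6, 2.16]
    )
    mouse_noise_sd: float = 0.22
    mouse_intercept_sd: float = 0.15

    def resolved_effects(self) -> dict:
        if self.effects is None:
            return _default_effects(list(self.cancer_types))
        return self.effects

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effects"] = self.resolved_effects()
        return d


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth that produced it."""

    data: pd.DataFrame
    truth: dict


def _skewnorm_params(median: float, cv: float, alpha: float):
    omega = cv * max(median, 0.05)
    xi = median - omega * stats.skewnorm.ppf(0.5, alpha)
    return xi, omega, alpha


def _fluid_medians(fluid: str) -> dict[str, float]:
    base = {c: _TRACE_MEDIAN for c in CONC_FEATURES}
    base.update(_PLASMA_MEDIANS if fluid == "plasma" else _URINE_MEDIANS)
    return base


def _draw_fluid_block(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    fluid: str,
    types: np.ndarray,
    batches: np.ndarray,
    batch_effects: dict[str, np.ndarray],
    extra_shift: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Draw the 17 concentrations for all samples of one fluid."""
    n = len(types)
    effects = cfg.resolved_effects()
    medians = _fluid_medians(fluid)
    vmult = cfg.variance_multipliers or {}
    cols = {}
    for feat in CONC_FEATURES:
        xi0, omega, alpha = _skewnorm_params(medians[feat], cfg.cv, cfg.alpha)
        shift = np.zeros(n)
        for i, t in enumerate(types):
            if t != "healthy":
                shift[i] = effects.get(t, {}).get(fluid, {}).get(feat, 0.0)
        shift = shift + batch_effects[fluid + ":" + feat][batches]
        if extra_shift is not None and feat in extra_shift:
            shift = shift + extra_shift[feat]
        scale = np.full(n, omega)
        for i in range(n):
            m = vmult.get(str(types[i]), {}) if vmult else {}
            scale[i] *= float(m.get(str(batches[i]), 1.0)) if isinstance(m, dict) else 1.0
        draws = stats.skewnorm.rvs(
            alpha, loc=xi0 + omega * shift, scale=scale, size=n, random_state=rng
        )
        draws = np.maximum(draws, 0.0)
        draws[draws < cfg.lod] = 0.0  # recorded below LOD
        cols[feat] = draws
    return pd.DataFrame(cols)


def _batch_effect_table(
    rng: np.random.Generator, cfg: GeneratorConfig
) -> dict[str, np.ndarray]:
    eff = {}
    for fluid in ("plasma", "urine"):
        for feat in CONC_FEATURES:
            eff[fluid + ":" + feat] = rng.normal(0.0, cfg.batch_sd, size=cfg.n_batches)
    return eff


def _stage_labels(
    rng: np.random.Generator, cfg: GeneratorConfig, subject_shift: np.ndarray
) -> np.ndarray:
    """Stage groups with a weak ordinal dependence on the planted effect size."""
    base_p = np.array([0.34, 0.10, 0.11, 0.45])
    cuts = stats.norm.ppf(np.cumsum(base_p)[:-1])
    z = (subject_shift - subject_shift.mean()) / (subject_shift.std() + 1e-12)
    latent = cfg.stage_slope * z + rng.normal(size=len(subject_shift))
    idx = np.searchsorted(cuts, latent)
    labels = np.array(["S1/LG", "S2", "S3", "S4/HG"])
    return labels[idx]


def _assemble(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    extra_shift_fn=None,
) -> tuple[pd.DataFrame, dict]:
    types = np.array(
        ["healthy"] * cfg.n_healthy
        + [t for t in cfg.cancer_types for _ in range(cfg.n_per_cancer_type)]
    )
    n = len(types)
    subject_ids = np.array([f"S{i:05d}" for i in range(n)])
    batches = rng.integers(0, cfg.n_batches, size=n)
    age = np.clip(rng.normal(62, 12, size=n), 21, 91).round(0)
    sex = rng.choice(["F", "M"], size=n)
    batch_eff = _batch_effect_table(rng, cfg)

    effects = cfg.resolved_effects()
    subject_shift = np.array(
        [
            0.0
            if t == "healthy"
            else sum(abs(v) for fl in effects.get(t, {}).values() for v in fl.values())
            for t in types
        ]
    ) * rng.uniform(0.6, 1.4, size=n)
    stage = np.where(
        types == "healthy", "", ""
    ).astype(object)
    cancer_mask = types != "healthy"
    stage[cancer_mask] = _stage_labels(rng, cfg, subject_shift[cancer_mask])

    rows = []
    extra = extra_shift_fn(rng, n) if extra_shift_fn is not None else {"plasma": None, "urine": None, "covariates": {}}
    for fluid in ("plasma", "urine"):
        block = _draw_fluid_block(
            rng, cfg, fluid, types, batches, batch_eff, extra_shift=extra[fluid]
        )
        meta = pd.DataFrame(
            {
                "sample_id": [f"{sid}_{fluid[0].upper()}" for sid in subject_ids],
                "subject_id": subject_ids,
                "fluid": fluid,
                "batch": [f"B{b+1}" for b in batches],
                "diagnosis": np.where(cancer_mask, "cancer", "healthy"),
                "cancer_type": np.where(cancer_mask, types, ""),
                "stage_group": stage,
                "age": age,
                "sex": sex,
            }
        )
        for cov, vals in extra["covariates"].items():
            meta[cov] = vals
        rows.append(pd.concat([meta, block], axis=1))
    data = pd.concat(rows, ignore_index=True)

    truth = {
        "effects": effects,
        "batch_effects": {k: v.tolist() for k, v in batch_eff.items()},
        "informative": sorted(
            {
                f"{fluid}_{feat}"
                for t, fl in effects.items()
                for fluid, fm in fl.items()
                for feat, v in fm.items()
                if v != 0.0
            }
        ),
        "config": cfg.to_dict(),
    }
    return data, truth


def generate_development_cohort(
    config: GeneratorConfig | None = None, seed: int = 0
) -> SyntheticCohort:
    """Case-control development cohort (both fluids per subject)."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    data, truth = _assemble(rng, cfg)
    return SyntheticCohort(data=data, truth=truth)


def generate_validation_cohort(
    config: GeneratorConfig | None = None, seed: int = 0
) -> SyntheticCohort:
    """External-style cohort with CRP and HDL-C confounders.

    CRP shifts the concentration features that drive the score upward
    (calibrated so the score-CRP Kendall tau is near its configured target);
    HDL-C shifts them downward.
    """
    cfg = config or GeneratorConfig()
    if abs(cfg.crp_effect) >= 5 or abs(cfg.hdl_effect) >= 5:
        raise ValueError("confounder effect out of range")

    conf_targets = {
        "plasma": ["cs_0s"],
        "urine": ["cs_0s", "hs_0s", "hs_ns", "cs_4s", "cs_6s"],
    }

    def extra_shift_fn(rng: np.random.Generator, n: int):
        log_crp = rng.normal(np.log(1.3), 0.7, size=n)
        crp = np.exp(log_crp)
        hdl = np.clip(rng.normal(1.4, 0.28, size=n), 0.5, 3.0)
        crp_z = (log_crp - np.log(1.3)) / 0.7
        hdl_z = (hdl - 1.4) / 0.28
        shift = cfg.crp_effect * crp_z + cfg.hdl_effect * hdl_z
        out = {"covariates": {"crp_mg_dl": np.round(crp, 2), "hdl_mmol_l": np.round(hdl, 2)}}
        for fluid in ("plasma", "urine"):
            out[fluid] = {feat: shift for feat in conf_targets[fluid]}
        return out

    rng = np.random.default_rng(seed)
    data, truth = _assemble(rng, cfg, extra_shift_fn=extra_shift_fn)
    truth["confounder_targets"] = conf_targets
    return SyntheticCohort(data=data, truth=truth)


def generate_survival(
    group_low: np.ndarray,
    hr_low_vs_high: float = 0.61,
    seed: int = 0,
    baseline_hazard: float = 0.03,
    weibull_shape: float = 1.0,
    event_fraction: float = 0.5,
) -> pd.DataFrame:
    """Survival times (months) for a high/low score grouping.

    Times follow a Weibull proportional-hazards model whose log-hazard is
    linear in the low-score indicator (planted hazard ratio
    ``hr_low_vs_high`` for low vs high); censoring is independent uniform,
    with the horizon solved numerically to hit ``event_fraction``.
    """
    group_low = np.asarray(group_low, dtype=bool)
    if event_fraction <= 0:
        raise ValueError("event_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(group_low)
    lam = baseline_hazard * np.where(group_low, hr_low_vs_high, 1.0)
    u = rng.uniform(size=n)
    t_event = (-np.log(u) / lam) ** (1.0 / weibull_shape)

    if event_fraction >= 1.0:
        return pd.DataFrame({"os_months": t_event, "os_event": np.ones(n, int)})

    def frac_events(c):
        cens = np.linspace(1e-6, c, 512)
        # P(T < C) averaged over C ~ U(0, c), per group, weighted
        f = 0.0
        for g, w in ((True, group_low.mean()), (False, 1 - group_low.mean())):
            l = baseline_hazard * (hr_low_vs_high if g else 1.0)
            surv = np.exp(-((l * cens) ** 1.0) if weibull_shape == 1.0 else -((l ** 1.0) * cens ** weibull_shape))
            f += w * (1.0 - surv.mean())
        return f

    lo, hi = 1e-3, 1e5
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        if frac_events(mid) < event_fraction:
            lo = mid
        else:
            hi = mid
    c_max = np.sqrt(lo * hi)
    t_cens = rng.uniform(0, c_max, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"os_months": time, "os_event": event})


def generate_mouse(
    config: GeneratorConfig | None = None,
    n_mice: int = 20,
    n_cages: int = 10,
    seed: int = 0,
    dropout: dict | None = None,
) -> SyntheticCohort:
    """Longitudinal mouse experiment: per-mouse plasma, per-cage pooled urine.

    Four timepoints (baseline, localized growth, post-operative resection,
    metastasis). 0S CS rises multiplicatively along the progression;
    ``dropout`` maps mouse id -> first timepoint index at which it is dead,
    which removes its plasma rows and marks its cage's pooled urine as not
    alive-paired from then on.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    dropout = dropout or {}
    mice = [f"M{i+1:02d}" for i in range(n_mice)]
    cages = {m: f"C{(i // 2) + 1:02d}" for i, m in enumerate(mice)}

    def draw_block(fluid, mult_by_tp, units, intercepts):
        medians = _fluid_medians(fluid)
        rows = []
        for tp_idx, tp in enumerate(TIMEPOINTS):
            for u in units:
                row = {"unit_id": u, "timepoint": tp, "fluid": fluid}
                for feat in CONC_FEATURES:
                    m = medians[feat]
                    mult = mult_by_tp[tp_idx] if feat == "cs_0s" else 1.0
                    val = (
                        m
                        * mult
                        * np.exp(intercepts[u] + rng.normal(0, cfg.mouse_noise_sd))
                    )
                    row[feat] = max(val, 0.0) if val >= cfg.lod else 0.0
                rows.append(row)
        return pd.DataFrame(rows)

    mouse_int = {m: rng.normal(0, cfg.mouse_intercept_sd) for m in mice}
    cage_ids = sorted(set(cages.values()))[:n_cages]
    cage_int = {c: rng.normal(0, cfg.mouse_intercept_sd) for c in cage_ids}

    plasma = draw_block("plasma", cfg.mouse_plasma_multipliers, mice, mouse_int)
    urine = draw_block("urine", cfg.mouse_urine_multipliers, cage_ids, cage_int)

    # apply dropout: dead mice lose plasma rows; cages lose the alive-pair flag
    dead_at = {m: dropout.get(m, len(TIMEPOINTS)) for m in mice}
    keep = [
        TIMEPOINTS.index(r.timepoint) < dead_at[r.unit_id]
        for r in plasma.itertuples()
    ]
    plasma = plasma[np.array(keep)].reset_index(drop=True)
    plasma["alive_pair"] = True

    def pair_alive(cage, tp_idx):
        members = [m for m in mice if cages[m] == cage]
        return all(tp_idx < dead_at[m] for m in members)

    urine["alive_pair"] = [
        pair_alive(r.unit_id, TIMEPOINTS.index(r.timepoint)) for r in urine.itertuples()
    ]
    data = pd.concat([plasma, urine], ignore_index=True)
    truth = {
        "plasma_multipliers": list(cfg.mouse_plasma_multipliers),
        "urine_multipliers": list(cfg.mouse_urine_multipliers),
        "pct_change_metastasis": {
            "plasma": 100.0 * (cfg.mouse_plasma_multipliers[-1] - 1.0),
            "urine": 100.0 * (cfg.mouse_urine_multipliers[-1] - 1.0),
        },
    }
    return SyntheticCohort(data=data, truth=truth)


def bayes_auc(
    config: GeneratorConfig | None = None,
    n: int = 4000,
    seed: int = 123,
    fluids: tuple = ("plasma", "urine"),
) -> float:
    """Oracle AUC of the generative log-likelihood-ratio score.

    Draws a fresh cohort and scores every sample with the exact
    log-likelihood ratio of cancer (equal-weight mixture over types) vs
    healthy under the generative skew-normal model, conditioning on the true
    batch effects and handling below-LOD records through the censored mass
    P(X < LOD). This is the best achievable discrimination under the study
    conditions; fitted scores are benchmarked against it.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    per_type = max(1, int(round(n / 2 / max(len(cfg.cancer_types), 1))))
    cfg_eval = GeneratorConfig(**{**cfg.to_dict(), "n_healthy": per_type * len(cfg.cancer_types), "n_per_cancer_type": per_type})
    cohort = generate_development_cohort(cfg_eval, seed=int(rng.integers(2**31 - 1)))
    data, truth = cohort.data, cohort.truth
    effects = truth["effects"]
    batch_eff = {k: np.asarray(v) for k, v in truth["batch_effects"].items()}

    def loglik(block, fluid, type_label):
        medians = _fluid_medians(fluid)
        batches = block["batch"].str.slice(1).astype(int).to_numpy() - 1
        total = np.zeros(len(block))
        for feat in CONC_FEATURES:
            xi0, omega, alpha = _skewnorm_params(medians[feat], cfg.cv, cfg.alpha)
            shift = 0.0
            if type_label != "healthy":
                shift = effects.get(type_label, {}).get(fluid, {}).get(feat, 0.0)
            loc = xi0 + omega * (shift + batch_eff[fluid + ":" + feat][batches])
            x = block[feat].to_numpy(dtype=float)
            obs = x >= cfg.lod
            ll = np.empty(len(block))
            ll[obs] = stats.skewnorm.logpdf(x[obs], alpha, loc=loc[obs], scale=omega)
            ll[~obs] = stats.skewnorm.logcdf(cfg.lod, alpha, loc=loc[~obs], scale=omega)
            total += ll
        return total

    llr_by_subject = {}
    labels = {}
    for fluid in fluids:
        block = data[data["fluid"] == fluid].reset_index(drop=True)
        ll_h = loglik(block, fluid, "healthy")
        ll_c = [loglik(block, fluid, t) for t in cfg.cancer_types]
        ll_cancer = np.logaddexp.reduce(np.vstack(ll_c), axis=0) - np.log(len(ll_c))
        llr = ll_cancer - ll_h
        for sid, v, d in zip(block["subject_id"], llr, block["diagnosis"]):
            llr_by_subject[sid] = llr_by_subject.get(sid, 0.0) + v
            labels[sid] = 1 if d == "cancer" else 0
    scores = np.array([llr_by_subject[s] for s in llr_by_subject])
    y = np.array([labels[s] for s in llr_by_subject])
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y, scores))
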