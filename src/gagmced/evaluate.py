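"""Discrimination and clinical-usefulness metrics, bootstrap internal
validation with optimism estimation, and confounder correlation tests.

AUC uses the rank (Mann-Whitney) statistic with tie correction; its CI comes
from the DeLong asymptotic covariance method. Sensitivity at a fixed
specificity anchors the cutoff on controls and reports a Wald binomial CI by
default (Clopper-Pearson exact optionally). PPV/NPV are the closed-form
screening identities at a stated prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .score import TPrior, fit_reference, forward_select, project_submodel, set_cutoffs


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(scores: np.ndarray, labels: np.ndarray, ci_level: float = 0.95) -> dict:
    """AUC with DeLong asymptotic CI.

    Returns ``{"auc", "ci_low", "ci_high", "se"}``; raises if only one class
    is present. Equals exhaustive pair counting (ties count 1/2) exactly.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v10 = (all_r[:m] - r_pos) / n
    v01 = 1.0 - (all_r[m:] - r_neg) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return {
        "auc": float(auc),
        "ci_low": float(max(0.0, auc - z * se)),
        "ci_high": float(min(1.0, auc + z * se)),
        "se": se,
    }


def binomial_ci(k: int, n: int, level: float = 0.95, method: str = "wald") -> tuple:
    """Binomial proportion CI (Wald approximation or Clopper-Pearson)."""
    p = k / n
    if method == "wald":
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(p * (1.0 - p) / n)
        return max(0.0, p - half), min(1.0, p + half)
    if method == "exact":
        a = (1.0 - level) / 2.0
        lo = 0.0 if k == 0 else stats.beta.ppf(a, k, n - k + 1)
        hi = 1.0 if k == n else stats.beta.ppf(1.0 - a, k + 1, n - k)
        return float(lo), float(hi)
    raise ValueError(f"unknown CI method {method!r}")


def sensitivity_at_specificity(
    scores: np.ndarray,
    labels: np.ndarray,
    specificity: float = 0.95,
    ci: str = "wald",
    cutoff: float | None = None,
) -> dict:
    """Sensitivity at a specificity-anchored cutoff, with binomial CI.

    The cutoff is fixed on the controls of this data unless given explicitly
    (subgroup analyses must pass the globally anchored cutoff).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    cases = scores[labels == 1]
    if len(cases) == 0:
        raise ValueError("no cases")
    if cutoff is None:
        controls = scores[labels == 0]
        if len(controls) == 0:
            raise ValueError("no controls to anchor the cutoff")
        cut = set_cutoffs(controls, (specificity,))
        cutoff = cut[f"spec{int(round(specificity * 100))}"]["cutoff"]
    detected = int(np.sum(cases > cutoff))
    sens = detected / len(cases)
    lo, hi = binomial_ci(detected, len(cases), method=ci)
    degenerate = detected in (0, len(cases)) and ci == "wald"
    return {
        "sensitivity": float(sens),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "detected": detected,
        "n_cases": len(cases),
        "cutoff": float(cutoff),
        "ci_method": ci,
        "degenerate_ci": degenerate,
    }


def ppv_npv(sens: float, spec: float, prevalence: float) -> tuple:
    """Screening arithmetic: post-test probabilities at a given prevalence."""
    for name, v in (("sens", sens), ("spec", spec), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    pi = prevalence
    denom_p = sens * pi + (1.0 - spec) * (1.0 - pi)
    denom_n = spec * (1.0 - pi) + (1.0 - sens) * pi
    ppv = sens * pi / denom_p if denom_p > 0 else np.nan
    npv = spec * (1.0 - pi) / denom_n if denom_n > 0 else np.nan
    return float(ppv), float(npv)


@dataclass
class EvalReport:
    auc: dict
    sensitivity: dict  # per specificity level
    subgroups: pd.DataFrame | None
    ppv_npv: dict
    n_cases: int
    n_controls: int


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    specificities: tuple = (0.95, 0.99),
    prevalence: float = 0.01,
    subgroup: np.ndarray | None = None,
    ci: str = "wald",
) -> EvalReport:
    """Full discrimination/usefulness report for one score.

    Subgroup sensitivities (e.g. stage groups or cancer types) reuse the
    cutoff anchored on *all* controls; they are never re-anchored per
    subgroup.
    """
    labels = np.asarray(labels).astype(int)
    auc = roc_auc(scores, labels)
    sens = {}
    for spec in specificities:
        sens[spec] = sensitivity_at_specificity(scores, labels, spec, ci=ci)
    pv = {}
    for spec in specificities:
        p, nv = ppv_npv(sens[spec]["sensitivity"], spec, prevalence)
        pv[spec] = {"ppv": p, "npv": nv, "prevalence": prevalence}
    sub = None
    if subgroup is not None:
        subgroup = np.asarray(subgroup)
        rows = []
        for spec in specificities:
            cutoff = sens[spec]["cutoff"]
            for g in pd.unique(subgroup[labels == 1]):
                mask = (subgroup == g) & (labels == 1)
                if mask.sum() == 0:
                    continue
                r = sensitivity_at_specificity(
                    np.asarray(scores)[mask],
                    np.ones(mask.sum(), int),
                    spec,
                    ci=ci,
                    cutoff=cutoff,
                )
                rows.append({"subgroup": g, "specificity": spec, **r})
        sub = pd.DataFrame(rows)
    return EvalReport(
        auc=auc,
        sensitivity=sens,
        subgroups=sub,
        ppv_npv=pv,
        n_cases=int(labels.sum()),
        n_controls=int((1 - labels).sum()),
    )


def scaled_brier(p: np.ndarray, y: np.ndarray) -> float:
    """Brier skill score against the prevalence-based reference predictor."""
    p = np.asarray(p, float)
    y = np.asarray(y, float)
    brier = float(np.mean((p - y) ** 2))
    pbar = float(np.mean(y))
    ref = pbar * (1.0 - pbar)
    return 1.0 - brier / ref if ref > 0 else np.nan


@dataclass
class BootstrapReport:
    B: int
    table: pd.DataFrame  # one row per bootstrap
    apparent: dict
    optimism: dict  # metric -> {"vs_original", "vs_assessment"}
    corrected: dict

    def summary(self) -> pd.DataFrame:
        return self.table.describe()


def bootstrap_validate(
    X: np.ndarray,
    y: np.ndarray,
    features: list,
    B: int = 100,
    prior: TPrior | None = None,
    cap: int | None = None,
    fluid_cap: int = 18,
    seed: int = 0,
    n_clusters: int = 10,
    sampler_opts: dict | None = None,
) -> BootstrapReport:
    """Bootstrap internal validation of the whole selection pipeline.

    Per bootstrap resample: refit the reference model (Student-t prior,
    df=3 by convention for this step), rerun forward selection with the size
    cap ``min(one-SE size, cases/10, fluid_cap)``, project, and record AUC,
    sensitivity at 95% specificity and scaled Brier on the bootstrap set,
    the original data, and the out-of-bag assessment set. Optimism is the
    mean bootstrap-minus-original (and bootstrap-minus-assessment)
    difference; corrected metrics subtract it from the apparent performance.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    prior = prior or TPrior(df=3.0, scale=2.5)
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    n = len(y)
    rng = np.random.default_rng(seed)
    opts = {"n_burn": 200, "n_steps": 120, **(sampler_opts or {})}

    def fit_and_score(Xtr, ytr, bseed):
        ref = fit_reference(
            Xtr, ytr, features=features, prior=prior, seed=bseed, **opts
        )
        hard_cap = min(
            int(np.floor(ytr.sum() / 10)) or 1, fluid_cap, cap or fluid_cap, len(features)
        )
        path = forward_select(ref, cap=hard_cap, n_clusters=n_clusters, seed=bseed + 1)
        sel = path.order[: path.chosen_size]
        proj = project_submodel(ref, sel, n_clusters=n_clusters, seed=bseed + 2)

        def predict(Xev):
            X1 = np.column_stack([np.ones(len(Xev)), Xev[:, sel]])
            eta = proj.thetas @ X1.T
            return (eta * proj.weights[:, None]).sum(axis=0), (
                expit(eta) * proj.weights[:, None]
            ).sum(axis=0)

        return predict, len(sel)

    def metrics(predict, Xev, yev):
        score, p = predict(Xev)
        out = {"auc": roc_auc(score, yev)["auc"], "brier_scaled": scaled_brier(p, yev)}
        try:
            out["sens95"] = sensitivity_at_specificity(score, yev, 0.95)["sensitivity"]
        except ValueError:
            out["sens95"] = np.nan
        return out

    predict_full, size_full = fit_and_score(X, y, int(rng.integers(2**31 - 1)))
    apparent = metrics(predict_full, X, y)
    apparent["size"] = size_full

    rows = []
    for b in range(B):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
        oob = np.setdiff1d(np.arange(n), idx)
        predict, size = fit_and_score(X[idx], y[idx], int(rng.integers(2**31 - 1)))
        row = {"b": b, "size": size}
        for tag, (Xe, ye) in {
            "boot": (X[idx], y[idx]),
            "orig": (X, y),
            "assess": (X[oob], y[oob]) if len(np.unique(y[oob])) == 2 else (None, None),
        }.items():
            if Xe is None:
                continue
            for k, v in metrics(predict, Xe, ye).items():
                row[f"{k}_{tag}"] = v
        rows.append(row)
    table = pd.DataFrame(rows)

    optimism, corrected = {}, {}
    for met in ("auc", "sens95", "brier_scaled"):
        d_orig = (table[f"{met}_boot"] - table[f"{met}_orig"]).mean()
        d_assess = (
            (table[f"{met}_boot"] - table[f"{met}_assess"]).mean()
            if f"{met}_assess" in table
            else np.nan
        )
        optimism[met] = {"vs_original": float(d_orig), "vs_assessment": float(d_assess)}
        corrected[met] = {
            "vs_original": float(apparent[met] - d_orig),
            "vs_assessment": float(apparent[met] - d_assess),
        }
    return BootstrapReport(
        B=B, table=table, apparent=apparent, optimism=optimism, corrected=corrected
    )


def kendall_confounder_test(
    score: np.ndarray,
    covariate: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Kendall tau with a permutation p-value.

    p = (1 + #{|tau_perm| >= |tau_hat|}) / (n_perm + 1). Ties are handled by
    tau-b. Raises on constant covariates.
    """
    score = np.asarray(score, float)
    covariate = np.asarray(covariate, float)
    if len(score) < 10:
        raise ValueError("need n >= 10")
    if n_perm < 999:
        raise ValueError("need n_perm >= 999")
    if np.all(covariate == covariate[0]):
        raise ValueError("constant covariate")
    tau = stats.kendalltau(score, covariate).statistic
    rng = np.random.default_rng(seed)
    count = 0
    cov = covariate.copy()
    for _ in range(n_perm):
        rng.shuffle(cov)
        t = stats.kendalltau(score, cov).statistic
        if abs(t) >= abs(tau) - 1e-15:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return {"tau": float(tau), "p_perm": float(p), "n_perm": n_perm}


def confounder_panel(
    score: np.ndarray,
    covariates: dict,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kendall permutation tests across covariates with Holm correction."""
    rows = []
    rng = np.random.default_rng(seed)
    for name, cov in covariates.items():
        r = kendall_confounder_test(score, cov, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
        rows.append({"covariate": name, **r})
    df = pd.DataFrame(rows)
    _, p_holm, _, _ = multipletests(df["p_perm"], alpha=alpha, method="holm")
    df["p_holm"] = p_holm
    df["significant"] = df["p_holm"] < alpha
    return df


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    return multipletests(np.asarray(pvals, float), method="holm")[1]
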