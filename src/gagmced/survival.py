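"""Overall-survival machinery: Kaplan-Meier, log-rank, Cox regression.

Everything here is computed from first principles (product-limit estimator,
hypergeometric log-rank moments, Newton-Raphson on the Efron partial
likelihood) so that the implementation can be validated against an
independent survival package on shared fixtures rather than delegating to
it. Times are months from sampling; events are all-cause death.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------- Kaplan-Meier

@dataclass
class KMCurve:
    time: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    median: float
    ci_low: np.ndarray
    ci_high: np.ndarray


def km_estimate(time, event) -> KMCurve:
    """Product-limit estimate with Greenwood log-log CIs and median."""
    time = np.asarray(time, float)
    event = np.asarray(event).astype(int)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq = np.unique(t[e == 1])
    n = len(t)
    surv, atrisk, nev, var_sum, lo, hi = [], [], [], 0.0, [], []
    s = 1.0
    for u in uniq:
        r = int(np.sum(t >= u))
        d = int(np.sum((t == u) & (e == 1)))
        s *= 1.0 - d / r
        if r > d:
            var_sum += d / (r * (r - d))
        atrisk.append(r)
        nev.append(d)
        surv.append(s)
        if 0 < s < 1 and var_sum > 0:
            se_cll = np.sqrt(var_sum) / abs(np.log(s))
            z = 1.959963984540054
            lo.append(s ** np.exp(z * se_cll))
            hi.append(s ** np.exp(-z * se_cll))
        else:
            lo.append(s)
            hi.append(s)
    surv = np.array(surv)
    median = float(uniq[surv <= 0.5][0]) if np.any(surv <= 0.5) else np.nan
    return KMCurve(
        time=uniq,
        survival=surv,
        at_risk=np.array(atrisk),
        events=np.array(nev),
        median=median,
        ci_low=np.array(lo),
        ci_high=np.array(hi),
    )


def median_followup(time, event) -> float:
    """Median follow-up by the reverse Kaplan-Meier method (censoring as
    the event of interest)."""
    event = np.asarray(event).astype(int)
    return km_estimate(time, 1 - event).median


def logrank_test(time, event, group) -> dict:
    """Log-rank test across two or more groups (hypergeometric moments)."""
    time = np.asarray(time, float)
    event = np.asarray(event).astype(int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) < 2:
        raise ValueError("need at least two non-empty groups")
    G = len(labels)
    uniq = np.unique(time[event == 1])
    O = np.zeros(G)
    E = np.zeros(G)
    V = np.zeros((G, G))
    for u in uniq:
        at = time >= u
        r = at.sum()
        d = int(np.sum((time == u) & (event == 1)))
        rg = np.array([(at & (group == g)).sum() for g in labels], float)
        dg = np.array(
            [int(np.sum((time == u) & (event == 1) & (group == g))) for g in labels]
        )
        O += dg
        E += d * rg / r
        if r > 1:
            c = d * (r - d) / (r - 1.0)
            for a in range(G):
                for b in range(G):
                    if a == b:
                        V[a, b] += c * (rg[a] / r) * (1.0 - rg[a] / r)
                    else:
                        V[a, b] -= c * rg[a] * rg[b] / r**2
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    chi2 = float(diff @ np.linalg.solve(Vsub + 1e-12 * np.eye(G - 1), diff))
    p = float(stats.chi2.sf(chi2, G - 1))
    return {"chi2": chi2, "df": G - 1, "p": p, "observed": O, "expected": E}


# ------------------------------------------------------------------- Cox model

@dataclass
class CoxFit:
    names: list
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    loglik: float
    loglik_null: float
    information: np.ndarray
    time: np.ndarray
    event: np.ndarray
    X: np.ndarray
    converged: bool
    warnings: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "HR": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "se": self.se,
                "p": self.p,
            },
            index=self.names,
        )


def _efron_loglik_deriv(beta, time, event, X):
    """Efron partial log-likelihood, gradient, and information."""
    n, p = X.shape
    order = np.argsort(-time, kind="stable")  # decreasing time
    t, e, Xs = time[order], event[order], X[order]
    eta = Xs @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    # cumulative risk-set sums while walking down in time
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        for idx in range(i, j):
            S0 += w[idx]
            S1 += w[idx] * Xs[idx]
            S2 += w[idx] * np.outer(Xs[idx], Xs[idx])
        died = [idx for idx in range(i, j) if e[idx] == 1]
        d = len(died)
        if d > 0:
            wd = w[died]
            Xd = Xs[died]
            D0 = wd.sum()
            D1 = (wd[:, None] * Xd).sum(axis=0)
            D2 = (wd[:, None, None] * Xd[:, :, None] * Xd[:, None, :]).sum(axis=0)
            ll += float(eta[died].sum())
            for l in range(d):
                f = l / d
                R0 = S0 - f * D0
                R1 = S1 - f * D1
                R2 = S2 - f * D2
                ll -= np.log(R0)
                grad -= R1 / R0
                info += R2 / R0 - np.outer(R1, R1) / R0**2
            grad += Xd.sum(axis=0)
        i = j
    return ll, grad, info


def cox_fit(
    time, event, X, names: list | None = None, max_iter: int = 50, tol: float = 1e-10
) -> CoxFit:
    """Newton-Raphson Cox proportional-hazards fit with Efron ties.

    Warns when there are fewer than ~10 events per covariate and flags
    monotone likelihood (suspected perfect separation).
    """
    time = np.asarray(time, float)
    event = np.asarray(event).astype(int)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(time):
        X = X.T
    n, p = X.shape
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    warn = []
    if event.sum() == 0:
        raise ValueError("no events")
    if event.sum() < 10 * p:
        warn.append(f"only {int(event.sum())} events for {p} covariates")

    beta = np.zeros(p)
    ll_null, _, _ = _efron_loglik_deriv(beta, time, event, X)
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        ll, grad, info = _efron_loglik_deriv(beta, time, event, X)
        try:
            step = np.linalg.solve(info + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        if np.linalg.norm(step) > 5.0:
            step *= 5.0 / np.linalg.norm(step)
        beta = beta + step
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
    ll, grad, info = _efron_loglik_deriv(beta, time, event, X)
    if np.abs(beta).max() > 10:
        warn.append("monotone likelihood suspected (|coef| > 10)")
    cov = np.linalg.inv(info + 1e-12 * np.eye(p))
    se = np.sqrt(np.diag(cov))
    z = beta / se
    return CoxFit(
        names=names,
        coef=beta,
        se=se,
        hr=np.exp(beta),
        ci_low=np.exp(beta - 1.959963984540054 * se),
        ci_high=np.exp(beta + 1.959963984540054 * se),
        p=2.0 * stats.norm.sf(np.abs(z)),
        loglik=float(ll),
        loglik_null=float(ll_null),
        information=info,
        time=time,
        event=event,
        X=X,
        converged=converged,
        warnings=warn,
    )


# ------------------------------------------------------- design-matrix helpers

def rcs_basis(x: np.ndarray, knots: np.ndarray | None = None) -> np.ndarray:
    """Restricted cubic spline basis with 3 knots (2 columns), scaled.

    Knots default to the 10/50/90% quantiles. Both columns are standardized
    to mean 0 / SD 1 so coefficients are comparable.
    """
    x = np.asarray(x, float)
    if knots is None:
        knots = np.quantile(x, [0.1, 0.5, 0.9])
    t1, t2, t3 = knots
    pos = lambda v: np.maximum(v, 0.0) ** 3
    nonlin = (
        pos(x - t1)
        - pos(x - t2) * (t3 - t1) / (t3 - t2)
        + pos(x - t3) * (t2 - t1) / (t3 - t2)
    ) / (t3 - t1) ** 2
    cols = np.column_stack([x, nonlin])
    return (cols - cols.mean(axis=0)) / cols.std(axis=0)


@dataclass
class SurvivalDesign:
    time: np.ndarray
    event: np.ndarray
    X: np.ndarray
    names: list
    n_dropped: int = 0


def build_design(
    df: pd.DataFrame,
    score_col: str = "score",
    extra_binary: dict | None = None,
) -> SurvivalDesign:
    """Multivariable design: score, splined age, sex, late stage, type flags.

    Rows with missing time/event/score/age are dropped (count recorded).
    ``extra_binary`` maps column name -> function(df) -> 0/1 array, e.g. the
    diffuse-glioma indicator used in plasma analyses.
    """
    need = [score_col, "os_months", "os_event", "age"]
    ok = df[need].notna().all(axis=1)
    d = df[ok]
    cols = [np.asarray(d[score_col], float)]
    names = [score_col]
    age_b = rcs_basis(d["age"].to_numpy(float))
    cols += [age_b[:, 0], age_b[:, 1]]
    names += ["age_rcs1", "age_rcs2"]
    if "sex" in d:
        cols.append((d["sex"].astype(str).str.upper().str[0] == "M").to_numpy(int))
        names.append("sex_male")
    if "stage_group" in d:
        cols.append((d["stage_group"] == "S4/HG").to_numpy(int))
        names.append("late_stage")
    for name, fn in (extra_binary or {}).items():
        cols.append(np.asarray(fn(d)).astype(int))
        names.append(name)
    return SurvivalDesign(
        time=d["os_months"].to_numpy(float),
        event=d["os_event"].to_numpy(int),
        X=np.column_stack(cols),
        names=names,
        n_dropped=int((~ok).sum()),
    )


# ------------------------------------------------------- dichotomized analysis

def dichotomize_and_compare(scores, cutoff, time, event) -> dict:
    """KM curves, log-rank p, and HR (low vs high) at a fixed score cutoff.

    The cutoff must be the globally anchored 95%-specificity cutoff; it is
    never re-derived on subsets.
    """
    scores = np.asarray(scores, float)
    low = scores <= cutoff
    if low.all() or (~low).all():
        raise ValueError("single stratum: all scores on one side of the cutoff")
    time = np.asarray(time, float)
    event = np.asarray(event).astype(int)
    fit = cox_fit(time, event, low.astype(float)[:, None], names=["low_score"])
    lr = logrank_test(time, event, np.where(low, "low", "high"))
    return {
        "hr_low_vs_high": float(fit.hr[0]),
        "ci_low": float(fit.ci_low[0]),
        "ci_high": float(fit.ci_high[0]),
        "logrank_p": lr["p"],
        "km_low": km_estimate(time[low], event[low]),
        "km_high": km_estimate(time[~low], event[~low]),
        "n_low": int(low.sum()),
        "n_high": int((~low).sum()),
    }


# ------------------------------------------------------------ diagnostics etc.

def ph_check(fit: CoxFit, transform: str = "km") -> dict:
    """Proportional-hazards check on scaled Schoenfeld residuals.

    Correlates each covariate's scaled residual with transformed event time
    (KM transform by default, identity optionally); per-covariate two-sided
    t-tests and a global chi-square.
    """
    time, event, X, beta = fit.time, fit.event, fit.X, fit.coef
    ev_idx = np.where(event == 1)[0]
    d = len(ev_idx)
    if d == 0:
        raise ValueError("no events")
    p = X.shape[1]
    resid = np.zeros((d, p))
    w = np.exp(X @ beta)
    for r, i in enumerate(ev_idx):
        at = time >= time[i]
        ws = w[at]
        xbar = (ws[:, None] * X[at]).sum(axis=0) / ws.sum()
        resid[r] = X[i] - xbar
    order = np.argsort(time[ev_idx], kind="stable")
    resid = resid[order]
    t_ev = np.sort(time[ev_idx])
    if transform == "km":
        km = km_estimate(time, event)
        g = 1.0 - np.interp(t_ev, km.time, km.survival)
    else:
        g = t_ev.copy()
    g = g - g.mean()
    scaled = d * resid @ np.linalg.inv(fit.information + 1e-12 * np.eye(p)) + beta
    rows = {}
    for j in range(p):
        r_corr = np.corrcoef(g, scaled[:, j])[0, 1]
        if abs(r_corr) >= 1.0 or d <= 2:
            pval = 0.0 if abs(r_corr) >= 1 else 1.0
        else:
            tstat = r_corr * np.sqrt((d - 2) / (1.0 - r_corr**2))
            pval = float(2.0 * stats.t.sf(abs(tstat), d - 2))
        rows[fit.names[j]] = pval
    u = resid.T @ g
    denom = float(g @ g)
    Vbar = fit.information / d
    chi2 = float(u @ np.linalg.solve(denom * Vbar + 1e-12 * np.eye(p), u))
    global_p = float(stats.chi2.sf(chi2, p))
    return {"per_covariate_p": rows, "global_chi2": chi2, "global_p": global_p}


def concordance(time, event, score) -> float:
    """Harrell's C for higher-score-implies-higher-risk orderings."""
    time = np.asarray(time, float)
    event = np.asarray(event).astype(int)
    score = np.asarray(score, float)
    n = len(time)
    num = den = 0.0
    for i in range(n):
        if event[i] != 1:
            continue
        later = (time > time[i]) | ((time == time[i]) & (event == 0))
        den += later.sum()
        num += (score[i] > score[later]).sum() + 0.5 * (score[i] == score[later]).sum()
    if den == 0:
        raise ValueError("no comparable pairs")
    return float(num / den)


def somers_dxy(time, event, score) -> float:
    return 2.0 * concordance(time, event, score) - 1.0


def cox_internal_validation(
    design: SurvivalDesign, B: int = 200, seed: int = 0
) -> dict:
    """Bootstrap optimism of Somers' Dxy for a multivariable Cox model.

    Per resample: refit, record Dxy on the resample minus Dxy of the same
    model on the original data; corrected Dxy subtracts the mean optimism.
    The relative correction (<20% conventionally acceptable) is reported.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    fit = cox_fit(design.time, design.event, design.X, names=design.names)
    lp = design.X @ fit.coef
    dxy_app = somers_dxy(design.time, design.event, lp)
    n = len(design.time)
    opts = []
    for _ in range(B):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            if design.event[idx].sum() >= max(3, design.X.shape[1]):
                break
        try:
            f = cox_fit(design.time[idx], design.event[idx], design.X[idx], names=design.names)
        except (ValueError, np.linalg.LinAlgError):
            continue
        d_boot = somers_dxy(design.time[idx], design.event[idx], design.X[idx] @ f.coef)
        d_orig = somers_dxy(design.time, design.event, design.X @ f.coef)
        opts.append(d_boot - d_orig)
    optimism = float(np.mean(opts))
    corrected = dxy_app - optimism
    correction_pct = 100.0 * abs(optimism) / abs(dxy_app) if dxy_app != 0 else np.inf
    return {
        "dxy_apparent": float(dxy_app),
        "optimism": optimism,
        "dxy_corrected": float(corrected),
        "correction_pct": float(correction_pct),
        "acceptable": bool(correction_pct < 20.0),
        "B_effective": len(opts),
    }
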