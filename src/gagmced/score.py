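"""MCED score construction by projection-predictive variable selection.

The reference model is a Bayesian logistic regression of cancer vs healthy
on standardized GAGome features with heavy-tailed Student-t(df, 0, scale)
priors on intercept and coefficients. Feature subsets are evaluated by
projecting the reference posterior onto each submodel — for each reference
draw the submodel coefficients minimize the KL divergence from the
reference's fitted Bernoulli probabilities, i.e. a logistic fit with soft
labels — and scoring the projected submodel with PSIS-LOO expected log
predictive density (ELPD). A greedy forward search orders features, the
one-standard-error rule picks the size, and the final model projects 400
reference draws. The score of a sample is the posterior-mean linear
predictor (log-odds of any-type cancer); cutoffs are anchored at fixed
specificity on controls.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from arviz import psislw
from scipy import optimize, stats
from scipy.special import expit, logsumexp
from sklearn.cluster import KMeans

from ._samplers import run_ensemble
from .features import CONC_FEATURES, Standardizer

MODEL_VERSION = "1"


@dataclass
class TPrior:
    df: float = 7.0
    scale: float = 2.5

    def logpdf(self, theta: np.ndarray) -> np.ndarray:
        return stats.t.logpdf(theta, self.df, loc=0.0, scale=self.scale).sum(axis=-1)

    def grad(self, theta: np.ndarray) -> np.ndarray:
        return -(self.df + 1.0) * theta / (self.df * self.scale**2 + theta**2)


@dataclass
class ReferenceModel:
    """Posterior of the full Bayesian logistic regression."""

    features: list
    X: np.ndarray  # (n, k) standardized, no intercept column
    y: np.ndarray
    draws: np.ndarray  # (S, k+1); column 0 is the intercept
    prior: TPrior
    ess: np.ndarray
    rhat: np.ndarray
    seed: int
    warnings: list = field(default_factory=list)
    _loo_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return len(self.y)

    def linpred(self, X: np.ndarray | None = None, draws: np.ndarray | None = None):
        X = self.X if X is None else X
        draws = self.draws if draws is None else draws
        X1 = np.column_stack([np.ones(len(X)), X])
        return draws @ X1.T  # (S, n)

    def pointwise_loglik(self) -> np.ndarray:
        eta = self.linpred()
        return self.y[None, :] * eta - np.logaddexp(0.0, eta)

    def psis_loo(self):
        """PSIS-LOO smoothed log-weights and pointwise reference ELPD."""
        if "lw" not in self._loo_cache:
            ll = self.pointwise_loglik()  # (S, n)
            lw, khat = psislw(-ll)
            elpd_i = logsumexp(lw + ll, axis=0)
            self._loo_cache.update(lw=lw, khat=khat, elpd_i=elpd_i)
        return self._loo_cache["lw"], self._loo_cache["elpd_i"]

    def draw_clusters(self, n_clusters: int, seed: int = 0):
        """Cluster posterior draws in prediction space (cached).

        Returns (labels, cluster_mean_probs, weights); used to bound the
        number of inner projection fits during the forward search.
        """
        key = ("clusters", n_clusters, seed)
        if key not in self._loo_cache:
            p_all = expit(self.linpred())
            km = KMeans(n_clusters=n_clusters, n_init=2, random_state=seed)
            labels = km.fit_predict(self.draws)
            pbar = np.vstack(
                [p_all[labels == c].mean(axis=0) for c in range(n_clusters)]
            )
            weights = np.bincount(labels, minlength=n_clusters) / len(labels)
            self._loo_cache[key] = (labels, pbar, weights)
        return self._loo_cache[key]

    def bayes_r2(self) -> float:
        """Bayesian R^2: var(fitted) / (var(fitted) + var(residual))."""
        p = expit(self.linpred())
        var_fit = p.var(axis=1)
        var_res = (p * (1 - p)).mean(axis=1)
        return float(np.mean(var_fit / (var_fit + var_res)))


def fit_reference(
    X: np.ndarray,
    y: np.ndarray,
    features: list | None = None,
    prior: TPrior | None = None,
    seed: int = 0,
    n_burn: int = 300,
    n_steps: int = 250,
    nwalkers: int | None = None,
    thin: int = 3,
) -> ReferenceModel:
    """Sample the reference logistic posterior with the ensemble sampler.

    Initialized at the MAP (found by L-BFGS on the log posterior). Flags
    suspected separation when coefficient draws wander far on the logit
    scale.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.ndim != 2 or np.isnan(X).any():
        raise ValueError("X must be a 2-D array without missing values")
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("y must be binary with both classes present")
    prior = prior or TPrior()
    n, k = X.shape
    X1 = np.column_stack([np.ones(n), X])
    feats = list(features) if features is not None else [f"x{j}" for j in range(k)]

    def neg_log_post(theta):
        eta = X1 @ theta
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        lp = float(prior.logpdf(theta[None, :])[0])
        g = X1.T @ (y - expit(eta)) + prior.grad(theta)
        return -(ll + lp), -g

    theta0 = np.zeros(k + 1)
    opt = optimize.minimize(neg_log_post, theta0, jac=True, method="L-BFGS-B")

    def log_prob(thetas):
        eta = thetas @ X1.T  # (W, n)
        ll = eta @ y - np.logaddexp(0.0, eta).sum(axis=1)
        return ll + prior.logpdf(thetas)

    res = run_ensemble(
        log_prob,
        opt.x,
        seed=seed,
        nwalkers=nwalkers,
        n_burn=n_burn,
        n_steps=n_steps,
        scatter=0.02,
        thin=thin,
    )
    warn = []
    if np.abs(res.draws).max() > 15.0:
        warn.append(
            "possible separation: coefficient draws exceed 15 on the logit "
            "scale; consider a heavier-tailed or tighter prior"
        )
    return ReferenceModel(
        features=feats,
        X=X,
        y=y,
        draws=res.draws,
        prior=prior,
        ess=res.ess,
        rhat=res.rhat,
        seed=seed,
        warnings=warn,
    )


def _soft_logistic_fit(X1: np.ndarray, p: np.ndarray, theta0: np.ndarray) -> np.ndarray:
    """Newton solver for the KL projection: logistic fit with soft labels p.

    The objective sum(log(1+exp(eta)) - p*eta) is convex; a backtracking
    (Armijo) line search on each Newton step guarantees monotone descent.
    A fixed step-length cap is not enough: far from the optimum the fitted
    probabilities saturate, the Hessian collapses, and capped full steps
    overshoot into a two-point limit cycle.
    """

    def obj(th):
        eta = X1 @ th
        return float(np.logaddexp(0.0, eta).sum() - p @ eta)

    theta = theta0.copy()
    f = obj(theta)
    for it in range(100):
        q = expit(X1 @ theta)
        grad = X1.T @ (q - p)
        if np.max(np.abs(grad)) < 1e-9:
            break
        W = np.clip(q * (1 - q), 1e-10, None)
        H = (X1 * W[:, None]).T @ X1
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(len(theta)), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        slope = float(grad @ step)
        t = 1.0
        f_new = obj(theta - step)
        while f_new > f - 1e-4 * t * slope and t > 1e-8:
            t *= 0.5
            f_new = obj(theta - t * step)
        if np.linalg.norm(t * step) < 1e-10:
            break
        theta = theta - t * step
        f = f_new
    return theta


@dataclass
class ProjectedDraws:
    """Projection of reference draws onto a feature subset."""

    subset: list  # indices into reference feature list
    thetas: np.ndarray  # (C, m+1) projected coefficients per draw cluster
    draw_to_cluster: np.ndarray  # (S,) mapping of reference draws to clusters
    weights: np.ndarray  # (C,) cluster fractions


def project_submodel(
    ref: ReferenceModel,
    subset: list,
    n_clusters: int | None = 20,
    seed: int = 0,
    thin_to: int | None = None,
) -> ProjectedDraws:
    """KL-project the reference posterior onto the features in ``subset``.

    With ``n_clusters`` set, reference draws are clustered (k-means on the
    fitted-probability vectors) and one projection is solved per cluster —
    the projection framework's standard efficiency device. With
    ``n_clusters=None`` every (optionally thinned) draw is projected
    individually, which makes projection onto the full feature set an exact
    identity.
    """
    subset = list(subset)
    S = len(ref.draws)
    X1 = np.column_stack([np.ones(ref.n), ref.X])
    cols = [0] + [j + 1 for j in subset]
    X1s = X1[:, cols]

    if n_clusters is None or n_clusters >= S:
        draws = ref.draws
        if thin_to is not None and thin_to < S:
            idx = np.linspace(0, S - 1, thin_to).round().astype(int)
            draws = draws[idx]
            S = len(draws)
        p_all = expit(draws @ X1.T)  # (S, n)
        thetas = np.empty((S, len(cols)))
        for s in range(S):
            thetas[s] = _soft_logistic_fit(X1s, p_all[s], draws[s, cols])
        return ProjectedDraws(
            subset=subset,
            thetas=thetas,
            draw_to_cluster=np.arange(S),
            weights=np.full(S, 1.0 / S),
        )

    labels, pbar, weights = ref.draw_clusters(n_clusters, seed=0)
    theta_init = ref.draws[:, cols].mean(axis=0)
    thetas = np.empty((n_clusters, len(cols)))
    for c in range(n_clusters):
        thetas[c] = _soft_logistic_fit(X1s, pbar[c], theta_init)
    return ProjectedDraws(
        subset=subset, thetas=thetas, draw_to_cluster=labels, weights=weights
    )


def _submodel_elpd(
    ref: ReferenceModel, proj: ProjectedDraws, lw: np.ndarray
) -> np.ndarray:
    """Pointwise PSIS-LOO ELPD of a projected submodel.

    Reference-draw importance weights are reused for the projected draws
    (each reference draw maps to its cluster's projection).
    """
    X1 = np.column_stack([np.ones(ref.n), ref.X])
    cols = [0] + [j + 1 for j in proj.subset]
    eta = proj.thetas @ X1[:, cols].T  # (C, n)
    ll_c = ref.y[None, :] * eta - np.logaddexp(0.0, eta)  # (C, n)
    S = lw.shape[0]
    if len(proj.thetas) == S and np.array_equal(proj.draw_to_cluster, np.arange(S)):
        ll = ll_c
    else:
        # lw has one row per reference draw; psis_loo uses the full draw set
        ll = ll_c[proj.draw_to_cluster[: S]]
    return logsumexp(lw + ll, axis=0)


@dataclass
class SelectionPath:
    features: list  # ordered feature names
    order: list  # ordered candidate indices
    elpd: list  # submodel ELPD per size
    elpd_diff: list  # ELPD(submodel) - ELPD(reference) per size
    se_diff: list
    elpd_ref: float
    chosen_size: int = 0
    rule: str = "one-se"
    warnings: list = field(default_factory=list)


def forward_select(
    ref: ReferenceModel,
    candidates: list | None = None,
    cap: int | None = None,
    n_clusters: int = 20,
    seed: int = 0,
) -> SelectionPath:
    """Greedy forward search maximizing cross-validated projected ELPD.

    Ties on ELPD are broken toward the candidate with the larger absolute
    posterior-mean reference coefficient, making the path deterministic
    given the draws.
    """
    k = ref.X.shape[1]
    cand = list(range(k)) if candidates is None else list(candidates)
    cap = min(cap if cap is not None else k, len(cand))
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if ref.n < 20:
        raise ValueError("too few observations for cross-validated selection")
    lw, elpd_ref_i = ref.psis_loo()
    elpd_ref = float(elpd_ref_i.sum())
    coef_mag = np.abs(ref.draws.mean(axis=0)[1:])

    selected: list[int] = []
    path = SelectionPath(
        features=[], order=[], elpd=[], elpd_diff=[], se_diff=[], elpd_ref=elpd_ref
    )
    remaining = list(cand)
    rng = np.random.default_rng(seed)
    while len(selected) < cap and remaining:
        best = None
        for j in remaining:
            proj = project_submodel(
                ref, selected + [j], n_clusters=n_clusters, seed=int(rng.integers(2**31 - 1))
            )
            elpd_i = _submodel_elpd(ref, proj, lw)
            tot = float(elpd_i.sum())
            key = (tot, coef_mag[j])
            if best is None or key > best[0]:
                best = (key, j, elpd_i)
        _, j_best, elpd_i = best
        selected.append(j_best)
        remaining.remove(j_best)
        diff_i = elpd_i - elpd_ref_i
        path.order.append(j_best)
        path.features.append(ref.features[j_best])
        path.elpd.append(float(elpd_i.sum()))
        path.elpd_diff.append(float(diff_i.sum()))
        path.se_diff.append(float(np.sqrt(len(diff_i)) * np.std(diff_i)))
    path.chosen_size = choose_size(path)
    return path


def choose_size(path: SelectionPath) -> int:
    """One-standard-error rule: smallest size with ELPD within 1 SE of the
    reference model's ELPD (i.e. difference >= -SE)."""
    for size, (d, se) in enumerate(zip(path.elpd_diff, path.se_diff), start=1):
        if d >= -se:
            return size
    path.warnings.append("no size within one SE of the reference; using the cap")
    return len(path.elpd_diff)


def set_cutoffs(
    control_scores: np.ndarray, specificities: tuple = (0.95, 0.99)
) -> dict:
    """Specificity-anchored score cutoffs on controls.

    A sample is called positive when its score is strictly greater than the
    cutoff; the cutoff is the smallest control score achieving at least the
    target specificity (ties broken upward). Achieved specificity is
    reported alongside.
    """
    s = np.sort(np.asarray(control_scores, float))
    n = len(s)
    if n == 0:
        raise ValueError("no control scores")
    out = {}
    for spec in specificities:
        if not 0 < spec <= 1:
            raise ValueError("specificity must be in (0, 1]")
        kth = int(np.ceil(spec * n))
        cut = float(s[kth - 1])
        achieved = float(np.mean(s <= cut))
        out[f"spec{int(round(spec * 100))}"] = {"cutoff": cut, "achieved_specificity": achieved}
    return out


@dataclass
class ProjectedScoreModel:
    """Final MCED score: selected features, 400 projected draws, cutoffs."""

    features: list
    draws: np.ndarray  # (400, m+1)
    standardization: Standardizer | None
    cutoffs: dict
    prior: dict
    seed: int
    display_cap: tuple = (-6.0, 6.0)
    version: str = MODEL_VERSION

    def score(self, X) -> np.ndarray:
        """Posterior-mean log-odds of any-type cancer per sample."""
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            if self.standardization is not None:
                X = self.standardization.transform(X)
            X = X[self.features].to_numpy(dtype=float)
        X1 = np.column_stack([np.ones(len(X)), X])
        return (self.draws @ X1.T).mean(axis=0)

    def classify(self, X, level: str = "spec95") -> np.ndarray:
        return self.score(X) > self.cutoffs[level]["cutoff"]

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "features": self.features,
                "projected_draws": self.draws.tolist(),
                "standardization": None
                if self.standardization is None
                else self.standardization.to_dict(),
                "cutoffs": self.cutoffs,
                "prior": self.prior,
                "seed": self.seed,
                "display_cap": list(self.display_cap),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ProjectedScoreModel":
        d = json.loads(text)
        if d.get("version") != MODEL_VERSION:
            raise ValueError(
                f"model version mismatch: file has {d.get('version')!r}, "
                f"expected {MODEL_VERSION!r}"
            )
        return cls(
            features=d["features"],
            draws=np.asarray(d["projected_draws"], float),
            standardization=None
            if d["standardization"] is None
            else Standardizer.from_dict(d["standardization"]),
            cutoffs=d["cutoffs"],
            prior=d["prior"],
            seed=d["seed"],
            display_cap=tuple(d["display_cap"]),
        )


def prune_to_independent(candidates: list) -> list:
    """Restrict candidates to independently measured concentration features.

    Concentration features are the 17 per-fluid ug/mL measurements (possibly
    carrying a ``plasma_``/``urine_`` prefix in combined tables); fractions,
    charges, totals and ratios are derived and are pruned away.
    """
    conc = set(CONC_FEATURES)

    def is_conc(name: str) -> bool:
        for pref in ("plasma_", "urine_"):
            if name.startswith(pref):
                name = name[len(pref):]
                break
        return name in conc

    pruned = [c for c in candidates if is_conc(c)]
    if not pruned:
        raise ValueError("no concentration features among candidates")
    return pruned


def build_score(
    X: np.ndarray,
    y: np.ndarray,
    features: list,
    cap: int | None = None,
    prior: TPrior | None = None,
    seed: int = 0,
    n_clusters: int = 20,
    standardization: Standardizer | None = None,
    specificities: tuple = (0.95, 0.99),
    n_projected_draws: int = 400,
    reference: ReferenceModel | None = None,
) -> tuple[ProjectedScoreModel, SelectionPath]:
    """End-to-end score construction on a training table.

    Fits the reference model, runs forward selection with the one-SE size
    rule, projects ``n_projected_draws`` reference draws onto the selected
    subset (per-draw, no clustering), and anchors cutoffs on the control
    scores.
    """
    prior = prior or TPrior()
    ref = reference or fit_reference(X, y, features=features, prior=prior, seed=seed)
    path = forward_select(ref, cap=cap, n_clusters=n_clusters, seed=seed + 1)
    sel = path.order[: path.chosen_size]
    proj = project_submodel(ref, sel, n_clusters=None, thin_to=n_projected_draws, seed=seed + 2)
    model = ProjectedScoreModel(
        features=[ref.features[j] for j in sel],
        draws=proj.thetas,
        standardization=standardization,
        cutoffs={},
        prior={"df": prior.df, "scale": prior.scale},
        seed=seed,
    )
    scores = model.score(np.asarray(X, float)[:, sel])
    model.cutoffs = set_cutoffs(scores[np.asarray(y) == 0], specificities)
    return model, path
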