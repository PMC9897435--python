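"""Posterior-sampling utilities shared across modules.

Two workhorses: a thin wrapper around the affine-invariant ensemble sampler
(emcee) with vectorized log-posteriors and arviz-based diagnostics, and a
conjugate Gibbs sampler for the normal linear mixed model with a single
random-intercept grouping factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import emcee
import numpy as np


@dataclass
class EnsembleResult:
    """Flattened posterior draws plus convergence diagnostics.

    ``draws`` has shape (n_draws, ndim); ``ess`` and ``rhat`` are per
    parameter, computed by treating walkers as chains (walkers interact, so
    R-hat is approximate; it is still a useful stuck-walker alarm).
    """

    draws: np.ndarray
    ess: np.ndarray
    rhat: np.ndarray
    acceptance: float

    def converged(self, min_ess: float = 400.0, max_rhat: float = 1.05) -> bool:
        return bool(np.min(self.ess) > min_ess and np.max(self.rhat) < max_rhat)


def run_ensemble(
    log_prob,
    init_center: np.ndarray,
    seed: int,
    nwalkers: int | None = None,
    n_burn: int = 400,
    n_steps: int = 400,
    scatter: float = 0.05,
    thin: int = 1,
) -> EnsembleResult:
    """Run emcee with a vectorized log-posterior.

    ``log_prob`` must accept a (walkers, ndim) array and return a (walkers,)
    array of log densities. Initialization is a Gaussian ball around
    ``init_center``.
    """
    ndim = len(init_center)
    if nwalkers is None:
        nwalkers = max(2 * ndim + 2, 24)
    nwalkers += nwalkers % 2
    rng = np.random.default_rng(seed)
    p0 = init_center[None, :] + scatter * rng.standard_normal((nwalkers, ndim))
    lp0 = log_prob(p0)
    bad = ~np.isfinite(lp0)
    tries = 0
    while bad.any() and tries < 50:
        p0[bad] = init_center[None, :] + 0.5 * scatter * rng.standard_normal(
            (bad.sum(), ndim)
        )
        lp0 = log_prob(p0)
        bad = ~np.isfinite(lp0)
        tries += 1
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob, vectorize=True, moves=moves)
    sampler.random_state = np.random.RandomState(
        int(rng.integers(2**31 - 1))
    ).get_state()
    sampler.run_mcmc(p0, n_burn + n_steps, progress=False)
    chain = sampler.get_chain(discard=n_burn, thin=thin)  # (steps, walkers, ndim)
    arr = np.moveaxis(chain, 1, 0)  # (walkers, steps, ndim) = (chain, draw, dim)
    ess = np.array([float(az.ess(arr[:, :, d])) for d in range(ndim)])
    rhat = np.array([float(az.rhat(arr[:, :, d])) for d in range(ndim)])
    return EnsembleResult(
        draws=chain.reshape(-1, ndim),
        ess=ess,
        rhat=rhat,
        acceptance=float(np.mean(sampler.acceptance_fraction)),
    )


def gibbs_lmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    seed: int = 0,
    n_draws: int = 2000,
    n_burn: int = 500,
    sigma2_prior: tuple = (2.0, 1.0),
    tau2_prior: tuple = (2.0, 0.5),
) -> dict:
    """Gibbs sampler for y = X beta + b[group] + eps.

    Flat prior on beta, b_j ~ N(0, tau^2), inverse-gamma priors on the two
    variances (shape, scale) — weakly informative for data on a standardized
    scale. Returns draws of beta, b, sigma2, tau2. Conjugate throughout, so
    draws are exact conditional samples.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    labels, gidx = np.unique(groups, return_inverse=True)
    n, p = X.shape
    q = len(labels)
    rng = np.random.default_rng(seed)

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX + 1e-10 * np.eye(p))
    chol_fixed = np.linalg.cholesky(XtX_inv)
    counts = np.bincount(gidx, minlength=q).astype(float)

    beta = XtX_inv @ (X.T @ y)
    b = np.zeros(q)
    sigma2, tau2 = 1.0, 0.25
    a_s, b_s = sigma2_prior
    a_t, b_t = tau2_prior

    out_beta = np.empty((n_draws, p))
    out_b = np.empty((n_draws, q))
    out_s2 = np.empty(n_draws)
    out_t2 = np.empty(n_draws)
    for it in range(n_burn + n_draws):
        ystar = y - b[gidx]
        mean_beta = XtX_inv @ (X.T @ ystar)
        beta = mean_beta + np.sqrt(sigma2) * (chol_fixed @ rng.standard_normal(p))
        resid = y - X @ beta
        rsum = np.bincount(gidx, weights=resid, minlength=q)
        post_var = 1.0 / (counts / sigma2 + 1.0 / tau2)
        post_mean = post_var * rsum / sigma2
        b = post_mean + np.sqrt(post_var) * rng.standard_normal(q)
        eps = resid - b[gidx]
        sigma2 = 1.0 / rng.gamma(a_s + n / 2.0, 1.0 / (b_s + 0.5 * float(eps @ eps)))
        tau2 = 1.0 / rng.gamma(a_t + q / 2.0, 1.0 / (b_t + 0.5 * float(b @ b)))
        if it >= n_burn:
            j = it - n_burn
            out_beta[j] = beta
            out_b[j] = b
            out_s2[j] = sigma2
            out_t2[j] = tau2
    return {
        "beta": out_beta,
        "b": out_b,
        "sigma2": out_s2,
        "tau2": out_t2,
        "group_labels": labels,
    }
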