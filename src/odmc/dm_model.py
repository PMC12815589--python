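"""Dirichlet-multinomial model fitted by per-group maximum likelihood.

Cluster probability vectors are taken as Dirichlet(alpha_g) draws and the
counts as multinomial given those probabilities, which inflates the
multinomial covariance by (m + alpha_g.) / (1 + alpha_g.) where
alpha_g. = sum_c alpha_gc.  Groups are independent, so the model is fitted
one group at a time by quasi-Newton maximisation over log alpha_g
(unconstrained), with a method-of-moments start and the observed-information
covariance of the log-shape estimates.

Because every within-category contrast row sums to zero, contrasts of log
expected probabilities equal the same contrasts of log shapes:
A log pi_g = A log(alpha_g / alpha_g.) = A log alpha_g.  The log-shape
parametrisation is therefore equivalent, for the comparisons built here, to
mean-parametrised formulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln

from .contrasts import ContrastPair, kronecker_map
from .model_fit import CountTable, FitError

__all__ = ["DMFit", "dm_loglik", "fit_dm", "dm_theta", "implied_dispersion"]

_LOG_ALPHA_CAP = np.log(1e8)


@dataclass
class DMFit:
    """Per-group Dirichlet-multinomial ML estimates on the log-shape scale."""

    alpha_hat: np.ndarray  # (G, C) shape parameters
    log_alpha: np.ndarray  # (G, C)
    vcov_log_alpha: np.ndarray  # (G*C, G*C), block diagonal over groups
    loglik: float
    converged: bool
    iterations: int
    boundary: np.ndarray  # (G,) True where alpha_g. hit the multinomial cap
    group_levels: list[str]

    @property
    def alpha_dot(self) -> np.ndarray:
        return self.alpha_hat.sum(axis=1)

    def mean_probs(self) -> np.ndarray:
        """E[pi_g] = alpha_g / alpha_g., one row per group."""
        return self.alpha_hat / self.alpha_dot[:, None]


def _dm_logpmf_terms(y: np.ndarray, alpha: np.ndarray) -> float:
    """Sum of DM log-pmfs for count rows y (n, C) at a single shape vector."""
    m = y.sum(axis=1)
    a_dot = alpha.sum()
    const = gammaln(m + 1).sum() - gammaln(y + 1).sum()
    core = (
        len(m) * gammaln(a_dot)
        - gammaln(m + a_dot).sum()
        + gammaln(y + alpha).sum()
        - len(m) * gammaln(alpha).sum()
    )
    return float(const + core)


def dm_loglik(ct: CountTable, alpha: np.ndarray) -> float:
    """Dirichlet-multinomial log-likelihood at a (G, C) shape matrix."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("all shape parameters must be positive")
    gi = ct.group_index
    total = 0.0
    for g in range(ct.n_groups):
        total += _dm_logpmf_terms(ct.counts[gi == g], alpha[g])
    return total


def _group_negloglik_grad(log_a: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    alpha = np.exp(log_a)
    m = y.sum(axis=1)
    a_dot = alpha.sum()
    n = len(m)
    ll = (
        n * gammaln(a_dot)
        - gammaln(m + a_dot).sum()
        + gammaln(y + alpha).sum()
        - n * gammaln(alpha).sum()
    )
    grad_alpha = (
        n * digamma(a_dot)
        - digamma(m + a_dot).sum()
        + digamma(y + alpha).sum(axis=0)
        - n * digamma(alpha)
    )
    return -ll, -grad_alpha * alpha


def _moment_start(y: np.ndarray) -> np.ndarray:
    """Method-of-moments initial log alpha from pooled proportions and
    the between-cluster inflation of the Pearson statistic."""
    m = y.sum(axis=1).astype(float)
    p = y.sum(axis=0) / m.sum()
    p = np.clip(p, 1e-6, None)
    p = p / p.sum()
    mu = m[:, None] * p
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(mu > 0, (y - mu) ** 2 / mu, 0.0).sum()
    df = max(y.size - len(m) - (y.shape[1] - 1), 1)
    phi = max(chi2 / df, 1.0 + 1e-6)
    m_bar = m.mean()
    if phi >= m_bar:
        a_dot = 0.5
    else:
        a_dot = (m_bar - phi) / (phi - 1.0)
    a_dot = float(np.clip(a_dot, 1e-2, 1e6))
    return np.log(a_dot * p)


def fit_dm(ct: CountTable, gtol: float = 1e-6, max_iter: int = 500) -> DMFit:
    """Fit the DM model by per-group ML over unconstrained log shapes.

    Requires at least 2 clusters per group and no category that is zero in
    every cluster of a group.  When a group shows no extra-multinomial
    variation the likelihood increases towards the multinomial boundary
    (alpha_g. -> infinity); estimates are then capped at alpha_g. = 1e8 and
    flagged.  The covariance of the log-shape estimates is the inverse
    observed information (central-difference Hessian, step 1e-4).
    """
    gi = ct.group_index
    G, C = ct.n_groups, ct.n_categories
    pooled = ct.group_counts()
    zero_cells = np.argwhere(pooled == 0)
    if len(zero_cells):
        pairs = [(ct.group_levels[g], ct.categories[c]) for g, c in zero_cells]
        raise FitError(
            f"all-zero group x category cells {pairs}; apply the zero-cell "
            "adjustment (zero_adjust module) before DM fitting"
        )
    log_alpha = np.zeros((G, C))
    blocks = []
    loglik = 0.0
    converged = True
    iterations = 0
    boundary = np.zeros(G, dtype=bool)
    for g in range(G):
        y = ct.counts[gi == g].astype(float)
        if y.shape[0] < 2:
            raise FitError(
                f"group {ct.group_levels[g]!r} has {y.shape[0]} cluster(s); "
                "DM fitting needs at least 2"
            )
        x0 = _moment_start(y)
        res = minimize(
            _group_negloglik_grad,
            x0,
            args=(y,),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-30.0, _LOG_ALPHA_CAP)] * C,
            options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
        )
        la = res.x
        iterations += res.nit
        # the likelihood flattens out well before the hard bound; any total
        # this large is indistinguishable from the multinomial limit
        at_cap = np.exp(la).sum() >= 1e5
        if at_cap:
            boundary[g] = True
            warnings.warn(
                f"group {ct.group_levels[g]!r}: alpha_g. at the multinomial "
                "cap (no detectable overdispersion)",
                stacklevel=2,
            )
        elif not res.success and np.max(np.abs(res.jac)) > 1e-3:
            raise FitError(
                f"DM fit failed for group {ct.group_levels[g]!r}: {res.message} "
                f"(gradient max-norm {np.max(np.abs(res.jac)):.3g})"
            )
        log_alpha[g] = la
        loglik += -res.fun
        blocks.append(_vcov_block(la, y))
    vcov = np.zeros((G * C, G * C))
    for g, blk in enumerate(blocks):
        vcov[g * C : (g + 1) * C, g * C : (g + 1) * C] = blk
    # add back the multinomial normalising constant omitted in optimisation
    m_all = ct.cluster_totals
    loglik += float(gammaln(m_all + 1).sum() - gammaln(ct.counts + 1).sum())
    return DMFit(
        alpha_hat=np.exp(log_alpha),
        log_alpha=log_alpha,
        vcov_log_alpha=vcov,
        loglik=loglik,
        converged=converged,
        iterations=iterations,
        boundary=boundary,
        group_levels=list(ct.group_levels),
    )


def _vcov_block(log_a: np.ndarray, y: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Inverse observed information in log alpha via central differences."""
    C = len(log_a)
    H = np.zeros((C, C))
    for j in range(C):
        e = np.zeros(C)
        e[j] = step
        _, gp = _group_negloglik_grad(log_a + e, y)
        _, gm = _group_negloglik_grad(log_a - e, y)
        H[:, j] = (gp - gm) / (2 * step)
    H = 0.5 * (H + H.T)
    return np.linalg.pinv(H)


def implied_dispersion(fit: DMFit, m: float | np.ndarray) -> np.ndarray:
    """Dispersion factor (m + alpha_g.) / (1 + alpha_g.) implied per group."""
    a_dot = fit.alpha_dot
    return (m + a_dot) / (1.0 + a_dot)


def dm_theta(fit: DMFit, cp: ContrastPair) -> tuple[np.ndarray, np.ndarray]:
    """Contrast estimates theta = (B (x) A) . stacked log alpha and their covariance.

    Row-centred A makes A log pi_g = A log alpha_g, so applying the Kronecker
    map directly to the log shapes yields the same log odds ratios as the
    mean parametrisation.
    """
    if not fit.converged:
        raise FitError("DM fit did not converge; cannot form contrasts")
    M = kronecker_map(cp)
    if M.shape[1] != fit.log_alpha.size:
        raise ValueError(
            f"contrast map expects {M.shape[1]} parameters, fit has {fit.log_alpha.size}"
        )
    theta = M @ fit.log_alpha.reshape(-1)
    vcov = M @ fit.vcov_log_alpha @ M.T
    return theta, vcov
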