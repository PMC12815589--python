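"""Simultaneous inference for log odds ratios: single-step max-t adjustment.

The contrast estimates theta_hat are asymptotically multivariate normal with
covariance V assembled from the per-group delta-method blocks
Sigma_g = m_g^{-1} (A Diag(pi_g)^{-1} A' - A 1 1' A'), inflated by the
dispersion factor phi.  Tests and simultaneous confidence intervals use the
equicoordinate two-sided quantile of a central multivariate t with the
estimated correlation R_hat and residual degrees of freedom df = N - n - P,
so one critical value q covers all K comparisons at joint level 1 - alpha.

Tail probabilities P(max_k |T_k| <= q) are rectangle probabilities of the
multivariate t (or normal for df = inf), evaluated with scipy's
quasi-Monte-Carlo integrator seeded for reproducibility; the critical value
is found by Brent root-finding bracketed between the unadjusted and the
Bonferroni quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import multivariate_normal, multivariate_t, norm
from scipy.stats import t as t_dist

from .contrasts import ContrastPair, kronecker_map
from .dispersion import estimate_phi
from .dm_model import dm_theta, fit_dm
from .model_fit import CountTable, FitError, MultinomialFit, fit_multinomial

__all__ = [
    "InferenceResult",
    "sigma_g",
    "assemble_V",
    "mvt_critical",
    "max_t_probability",
    "adjusted_pvalues",
    "simultaneous_cis",
    "run_inference",
]

MAX_COMPARISONS = 1000


@dataclass
class InferenceResult:
    """Joint estimates, max-t adjusted p-values and simultaneous intervals."""

    labels: list[str]
    theta_hat: np.ndarray
    V_hat: np.ndarray
    R_hat: np.ndarray
    se: np.ndarray
    t_stats: np.ndarray
    df: float
    crit: float
    p_adj: np.ndarray
    ci_lower: np.ndarray  # on the odds-ratio (exp) scale
    ci_upper: np.ndarray
    alpha_level: float
    model: str
    phi_hat: float | None = None
    dispersion_method: str | None = None
    mc_seed: int | None = None
    mc_tol: float = 1e-4
    extra: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return len(self.theta_hat)

    @property
    def reject(self) -> np.ndarray:
        return np.abs(self.t_stats) > self.crit


def sigma_g(pi_g: np.ndarray, m_g: float, A: np.ndarray) -> np.ndarray:
    """Asymptotic covariance of the within-group log odds delta_g = A log pi_g.

    Sigma_g = m_g^{-1} (A Diag(pi_g)^{-1} A' - A 1 1' A'); the second term
    vanishes for row-centred A but is evaluated as written.
    """
    pi_g = np.asarray(pi_g, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.any(pi_g <= 0):
        raise FitError(
            "zero fitted probability; apply the zero-cell adjustment "
            "(zero_adjust module) before inference"
        )
    if m_g <= 0:
        raise ValueError("m_g must be positive")
    ones = np.ones((len(pi_g), 1))
    core = A @ np.diag(1.0 / pi_g) @ A.T - (A @ ones) @ (ones.T @ A.T)
    return core / m_g


def assemble_V(sigmas: list[np.ndarray], B: np.ndarray, phi: float = 1.0) -> np.ndarray:
    """Covariance of theta_hat: V = (B (x) I_I) blockdiag(phi Sigma_g) (B (x) I_I)'."""
    if phi <= 0:
        raise ValueError("phi must be positive")
    B = np.asarray(B, dtype=float)
    G = B.shape[1]
    if len(sigmas) != G:
        raise ValueError(f"need {G} Sigma_g blocks, got {len(sigmas)}")
    I = sigmas[0].shape[0]
    for s in sigmas:
        if s.shape != (I, I):
            raise ValueError("Sigma_g blocks must share dimensions")
    big = np.zeros((G * I, G * I))
    for g, s in enumerate(sigmas):
        big[g * I : (g + 1) * I, g * I : (g + 1) * I] = phi * s
    M = np.kron(B, np.eye(I))
    return M @ big @ M.T


def _correlation(V: np.ndarray) -> np.ndarray:
    se = np.sqrt(np.diag(V))
    if np.any(se <= 0):
        raise FitError("non-positive variance in V_hat")
    R = V / np.outer(se, se)
    np.fill_diagonal(R, 1.0)
    return R


def _repair_correlation(R: np.ndarray) -> np.ndarray:
    """Clip non-positive eigenvalues and restandardise; warns when needed."""
    w, U = np.linalg.eigh(R)
    if w.min() > 1e-10:
        return R
    warnings.warn(
        f"correlation matrix not positive definite (min eigenvalue {w.min():.2e}); "
        "clipping eigenvalues",
        stacklevel=3,
    )
    w = np.clip(w, 1e-10, None)
    R2 = U @ np.diag(w) @ U.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return R2


def max_t_probability(
    q: float | np.ndarray,
    df: float,
    R: np.ndarray,
    seed: int | None = 0,
    tol: float = 1e-4,
) -> float:
    """P(max_k |T_k| <= q) for a central multivariate t(df, R) (normal at df=inf).

    Quasi-Monte-Carlo rectangle probability; deterministic for a given seed.
    """
    R = np.asarray(R, dtype=float)
    K = R.shape[0]
    if K > MAX_COMPARISONS:
        raise ValueError(
            f"{K} comparisons exceed the supported maximum of {MAX_COMPARISONS}; "
            "consider a Bonferroni adjustment instead"
        )
    q = float(q)
    if q <= 0:
        return 0.0
    if K == 1:
        if np.isinf(df):
            return float(2 * norm.cdf(q) - 1)
        return float(2 * t_dist.cdf(q, df) - 1)
    R = _repair_correlation(R)
    upper = np.full(K, q)
    lower = -upper
    # the integrator's default point budget reaches ~5e-5 absolute accuracy;
    # only raise it for tighter tolerances
    maxpts = None if tol >= 1e-4 else max(int(1.0 / tol) * K, 10_000)
    rng = np.random.default_rng(seed)
    if np.isinf(df):
        kwargs = {} if maxpts is None else {"maxpts": maxpts}
        p = multivariate_normal.cdf(
            upper, mean=np.zeros(K), cov=R, lower_limit=lower, rng=rng, **kwargs
        )
    else:
        kwargs = {} if maxpts is None else {"maxpts": maxpts}
        p = multivariate_t.cdf(
            upper, loc=np.zeros(K), shape=R, df=df, lower_limit=lower,
            random_state=rng, **kwargs,
        )
    return float(min(max(p, 0.0), 1.0))


def mvt_critical(
    alpha_level: float,
    K: int,
    df: float,
    R: np.ndarray,
    seed: int | None = 0,
    tol: float = 1e-4,
) -> float:
    """Equicoordinate two-sided 1-alpha quantile of the multivariate t(df, R).

    Solves P(max_k |T_k| <= q) = 1 - alpha by Brent root-finding between the
    unadjusted and Bonferroni two-sided quantiles (which bracket the root for
    any correlation structure).
    """
    if not 0 < alpha_level < 1:
        raise ValueError("alpha_level must be in (0, 1)")
    if K > MAX_COMPARISONS:
        raise ValueError(
            f"{K} comparisons exceed the supported maximum of {MAX_COMPARISONS}; "
            "consider a Bonferroni adjustment instead"
        )
    dist = norm if np.isinf(df) else t_dist
    args = () if np.isinf(df) else (df,)
    lo = dist.ppf(1 - alpha_level / 2, *args)
    if K == 1:
        return float(lo)
    hi = dist.ppf(1 - alpha_level / (2 * K), *args)

    def g(q: float) -> float:
        return max_t_probability(q, df, R, seed=seed, tol=tol) - (1 - alpha_level)

    g_lo, g_hi = g(lo), g(hi)
    if g_lo >= 0:
        return float(lo)
    if g_hi <= 0:
        return float(hi)
    return float(optimize.brentq(g, lo, hi, xtol=1e-5, rtol=1e-8))


def adjusted_pvalues(
    t_stats: np.ndarray,
    df: float,
    R: np.ndarray,
    seed: int | None = 0,
    tol: float = 1e-4,
) -> np.ndarray:
    """Single-step adjusted p-values p_k = 1 - P(max_j |T_j| <= |t_k|)."""
    t_stats = np.asarray(t_stats, dtype=float)
    return np.array(
        [1.0 - max_t_probability(abs(t), df, R, seed=seed, tol=tol) for t in t_stats]
    )


def simultaneous_cis(
    theta_hat: np.ndarray, se: np.ndarray, crit: float
) -> tuple[np.ndarray, np.ndarray]:
    """Simultaneous intervals exp(theta_k +/- q * se_k) on the odds-ratio scale."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    return np.exp(theta_hat - crit * se), np.exp(theta_hat + crit * se)


def run_inference(
    ct: CountTable,
    cp: ContrastPair,
    model: str = "quasi",
    dispersion_method: str = "afroz",
    alpha_level: float = 0.05,
    seed: int | None = 0,
    tol: float = 1e-4,
    df: float | None = None,
    fit: MultinomialFit | None = None,
    compute_pvalues: bool = True,
    compute_crit: bool = True,
) -> InferenceResult:
    """Full pipeline: fit, dispersion, contrasts, max-t adjustment, intervals.

    ``model`` is one of ``plain`` (phi fixed at 1), ``quasi`` (phi estimated
    by ``dispersion_method``) or ``dm`` (Dirichlet-multinomial likelihood).
    ``df`` overrides the residual degrees of freedom (use ``np.inf`` for
    normal-based quantiles).  ``compute_pvalues`` / ``compute_crit`` allow
    simulation harnesses to skip the quantile computations they do not need.
    """
    if model not in ("plain", "quasi", "dm"):
        raise ValueError(f"unknown model {model!r}")
    if cp.C != ct.n_categories or cp.G != ct.n_groups:
        raise ValueError(
            f"contrast dimensions (C={cp.C}, G={cp.G}) do not match data "
            f"(C={ct.n_categories}, G={ct.n_groups})"
        )
    mfit = fit if fit is not None else fit_multinomial(ct)
    df_resid = mfit.df_residual
    phi_hat: float | None = None

    if model == "dm":
        dfit = fit_dm(ct)
        theta, V = dm_theta(dfit, cp)
        extra = {"dm_fit": dfit}
    else:
        if model == "quasi":
            est = estimate_phi(mfit, ct, dispersion_method)
            phi = phi_hat = est.phi_hat
        else:
            phi = 1.0
        M = kronecker_map(cp)
        with np.errstate(divide="ignore"):
            log_pi = np.log(mfit.pi_hat)
        if not np.all(np.isfinite(log_pi)):
            raise FitError(
                "zero fitted probability; apply the zero-cell adjustment "
                "(zero_adjust module) before inference"
            )
        theta = M @ log_pi.reshape(-1)
        group_m = np.zeros(ct.n_groups)
        np.add.at(group_m, ct.group_index, ct.cluster_totals)
        sigmas = [sigma_g(mfit.pi_hat[g], group_m[g], cp.A) for g in range(ct.n_groups)]
        V = assemble_V(sigmas, cp.B, phi)
        extra = {}

    se = np.sqrt(np.diag(V))
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise FitError("non-positive or non-finite standard errors")
    R = _correlation(V)
    t_stats = theta / se
    use_df = df_resid if df is None else df
    crit = (
        mvt_critical(alpha_level, cp.K, use_df, R, seed=seed, tol=tol)
        if compute_crit
        else np.nan
    )
    p_adj = (
        adjusted_pvalues(t_stats, use_df, R, seed=seed, tol=tol)
        if compute_pvalues
        else np.full(cp.K, np.nan)
    )
    lower, upper = (
        simultaneous_cis(theta, se, crit) if compute_crit else (np.full(cp.K, np.nan),) * 2
    )
    return InferenceResult(
        labels=cp.comparison_labels,
        theta_hat=theta,
        V_hat=V,
        R_hat=R,
        se=se,
        t_stats=t_stats,
        df=use_df,
        crit=crit,
        p_adj=p_adj,
        ci_lower=lower,
        ci_upper=upper,
        alpha_level=alpha_level,
        model=model,
        phi_hat=phi_hat,
        dispersion_method=dispersion_method if model == "quasi" else None,
        mc_seed=seed,
        mc_tol=tol,
        extra=extra,
    )
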