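"""Baseline-category multinomial model for clustered count tables.

Data enter as long-format records (group, cluster, category, count); each
cluster contributes a full multinomial count vector over the C categories.
With group as the only factor the maximum-likelihood fit is closed form
(pooled group proportions); with additive cluster-level factors the
baseline-category logit likelihood is maximised numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "CountTable",
    "MultinomialFit",
    "read_counts",
    "fit_multinomial",
    "fit_multinomial_glm",
    "pearson_stat",
    "deviance_stat",
]


class DataError(ValueError):
    """Invalid count data."""


class FitError(RuntimeError):
    """Model fitting failure."""


class ZeroCellError(FitError):
    """A fitted expected count is zero; see the zero_adjust module."""


@dataclass
class CountTable:
    """Clustered multinomial counts, densified to a clusters x categories grid.

    ``counts[i, c]`` is the count for cluster i (a row of ``clusters``) in
    category ``categories[c]``.  Clusters are nested in groups; extra
    cluster-level columns (e.g., a block factor) ride along in ``covariates``.
    """

    counts: np.ndarray  # (n_clusters, C) non-negative integers
    groups: np.ndarray  # (n_clusters,) group label per cluster
    clusters: np.ndarray  # (n_clusters,) cluster label per cluster
    categories: list[str]
    group_levels: list[str] = field(default=None)  # type: ignore[assignment]
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise DataError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise DataError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.group_levels is None:
            self.group_levels = list(pd.unique(self.groups))

    @property
    def n_clusters(self) -> int:
        return self.counts.shape[0]

    @property
    def n_categories(self) -> int:
        return self.counts.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_levels)

    @property
    def cluster_totals(self) -> np.ndarray:
        """m_gb: total units per cluster."""
        return self.counts.sum(axis=1)

    @property
    def group_index(self) -> np.ndarray:
        """0-based group index per cluster, following group_levels order."""
        lookup = {g: i for i, g in enumerate(self.group_levels)}
        return np.array([lookup[g] for g in self.groups])

    def group_counts(self) -> np.ndarray:
        """Pooled counts per group, shape (G, C)."""
        out = np.zeros((self.n_groups, self.n_categories), dtype=np.int64)
        np.add.at(out, self.group_index, self.counts)
        return out

    @property
    def group_totals(self) -> np.ndarray:
        """m_g: total units per group."""
        return self.group_counts().sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame (group, cluster, category, count)."""
        rows = []
        for i in range(self.n_clusters):
            for c, cat in enumerate(self.categories):
                rows.append((self.groups[i], self.clusters[i], cat, self.counts[i, c]))
        return pd.DataFrame(rows, columns=["group", "cluster", "category", "count"])

    def with_counts(self, counts: np.ndarray) -> "CountTable":
        return CountTable(
            counts=counts,
            groups=self.groups.copy(),
            clusters=self.clusters.copy(),
            categories=list(self.categories),
            group_levels=list(self.group_levels),
            covariates=None if self.covariates is None else self.covariates.copy(),
        )


def from_frame(df: pd.DataFrame, category_order: list[str] | None = None) -> CountTable:
    """Densify a long-format frame into a CountTable.

    Missing (group, cluster, category) cells are filled with zero counts.
    Category order defaults to first appearance in the file.
    """
    required = {"group", "cluster", "category", "count"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"missing required columns: {sorted(missing)}")
    counts_col = df["count"]
    if counts_col.isna().any():
        raise DataError("count column contains missing values")
    as_float = counts_col.astype(float)
    if np.any(as_float < 0) or not np.allclose(as_float, np.round(as_float)):
        raise DataError("counts must be non-negative integers")
    if df.duplicated(subset=["group", "cluster", "category"]).any():
        raise DataError("duplicate (group, cluster, category) rows")

    categories = category_order or list(pd.unique(df["category"]))
    unknown = set(df["category"]) - set(categories)
    if unknown:
        raise DataError(f"categories not in category_order: {sorted(unknown)}")
    group_levels = list(pd.unique(df["group"]))

    extra = [c for c in df.columns if c not in required]
    key = df[["group", "cluster"]].astype(str).agg("\x1f".join, axis=1)
    cluster_keys = list(pd.unique(key))
    idx = {k: i for i, k in enumerate(cluster_keys)}
    n, C = len(cluster_keys), len(categories)
    counts = np.zeros((n, C), dtype=np.int64)
    cat_idx = {c: j for j, c in enumerate(categories)}
    rows_i = key.map(idx).to_numpy(dtype=np.int64)
    rows_j = df["category"].map(cat_idx).to_numpy(dtype=np.int64)
    counts[rows_i, rows_j] = np.round(as_float).astype(np.int64)

    first = df.loc[~key.duplicated()].set_index(key[~key.duplicated()])
    first = first.loc[cluster_keys]
    covariates = None
    if extra:
        covariates = first[extra].reset_index(drop=True)
        # covariates must be constant within a cluster
        for col in extra:
            per = df.groupby(["group", "cluster"])[col].nunique()
            if (per > 1).any():
                raise DataError(f"covariate {col!r} varies within a cluster")
    return CountTable(
        counts=counts,
        groups=first["group"].to_numpy(),
        clusters=first["cluster"].to_numpy(),
        categories=categories,
        group_levels=group_levels,
        covariates=covariates,
    )


def read_counts(path: str | Path, category_order: list[str] | None = None) -> CountTable:
    """Read a long-format CSV (group, cluster, category, count) into a CountTable."""
    df = pd.read_csv(path)
    return from_frame(df, category_order=category_order)


@dataclass
class MultinomialFit:
    """A fitted baseline-category multinomial model.

    ``pi_hat`` holds one probability row per group (group-only design) while
    ``cluster_probs`` holds the per-cluster fitted rows used for expected
    counts (identical rows within a group when there are no covariates).
    ``beta`` follows the baseline-category convention: category 1 is the
    baseline and group 1 the reference, so the first C-1 entries are the
    reference-group log odds and the remaining blocks are log odds ratios
    versus the reference group.
    """

    pi_hat: np.ndarray  # (G, C)
    beta: np.ndarray  # (G*(C-1),)
    expected: np.ndarray  # (n_clusters, C) fitted expected counts
    cluster_probs: np.ndarray  # (n_clusters, C)
    N: int  # total cells n*C
    n: int  # total clusters
    P: int  # non-redundant parameters
    loglik: float
    converged: bool = True
    n_iter: int = 0
    coef: np.ndarray | None = None  # (p, C-1) when fit via a design matrix

    @property
    def df_residual(self) -> int:
        return self.N - self.n - self.P


def _beta_from_pi(pi: np.ndarray) -> np.ndarray:
    """Baseline-category parameter vector from a (G, C) probability table."""
    with np.errstate(divide="ignore"):
        logits = np.log(pi[:, 1:]) - np.log(pi[:, :1])  # (G, C-1)
    beta = logits.copy()
    beta[1:] -= logits[0]
    return beta.reshape(-1)


def fit_multinomial(ct: CountTable) -> MultinomialFit:
    """Closed-form ML fit with group as the only factor.

    The MLE pools counts within each group: pi_hat[g, c] = sum_b y_gbc / m_g.
    """
    pooled = ct.group_counts().astype(float)
    m_g = pooled.sum(axis=1)
    if np.any(m_g <= 0):
        bad = [ct.group_levels[i] for i in np.flatnonzero(m_g <= 0)]
        raise FitError(f"groups with zero total count: {bad}; remove them before fitting")
    pi_hat = pooled / m_g[:, None]
    gi = ct.group_index
    cluster_probs = pi_hat[gi]
    expected = cluster_probs * ct.cluster_totals[:, None]
    n = ct.n_clusters
    C = ct.n_categories
    G = ct.n_groups
    loglik = _multinomial_loglik(ct.counts, cluster_probs)
    return MultinomialFit(
        pi_hat=pi_hat,
        beta=_beta_from_pi(pi_hat),
        expected=expected,
        cluster_probs=cluster_probs,
        N=n * C,
        n=n,
        P=G * (C - 1),
        loglik=loglik,
    )


def _multinomial_loglik(y: np.ndarray, probs: np.ndarray) -> float:
    m = y.sum(axis=1)
    const = gammaln(m + 1).sum() - gammaln(y + 1).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(y > 0, y * np.log(probs), 0.0)
    return float(const + terms.sum())


def _design_matrix(ct: CountTable, formula: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + drop-first dummy coding for group and additive factors."""
    factors = list(formula)
    if "group" not in factors:
        factors = ["group"] + factors
    data = {}
    for f in factors:
        if f == "group":
            data[f] = pd.Categorical(ct.groups, categories=ct.group_levels)
        else:
            if ct.covariates is None or f not in ct.covariates.columns:
                raise FitError(f"unknown factor {f!r}")
            data[f] = pd.Categorical(ct.covariates[f])
    X = pd.get_dummies(pd.DataFrame(data), drop_first=True).astype(float)
    X.insert(0, "intercept", 1.0)
    return X.to_numpy(), list(X.columns)


def fit_multinomial_glm(
    ct: CountTable,
    formula: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> MultinomialFit:
    """Baseline-category logit fit with additive factor covariates.

    Maximises the multinomial log-likelihood by Newton iteration on the
    stacked coefficient matrix (p predictors x C-1 non-baseline categories).
    With group as the only factor this reproduces the closed-form pooled
    proportions.  Convergence: max |score| < tol.
    """
    if not formula:
        return fit_multinomial(ct)
    X, names = _design_matrix(ct, formula)
    y = ct.counts.astype(float)
    m = ct.cluster_totals.astype(float)
    n, C = y.shape
    p = X.shape[1]
    theta = np.zeros((p, C - 1))

    def eta_probs(theta: np.ndarray) -> np.ndarray:
        eta = np.concatenate([np.zeros((n, 1)), X @ theta], axis=1)
        return np.exp(eta - logsumexp(eta, axis=1, keepdims=True))

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        probs = eta_probs(theta)
        resid = y[:, 1:] - m[:, None] * probs[:, 1:]  # (n, C-1)
        score = X.T @ resid  # (p, C-1)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        # Fisher information for the stacked vec(theta), block (c, d)
        H = np.zeros((p * (C - 1), p * (C - 1)))
        for c in range(C - 1):
            for d in range(C - 1):
                w = m * probs[:, c + 1] * ((1.0 if c == d else 0.0) - probs[:, d + 1])
                H[c * p : (c + 1) * p, d * p : (d + 1) * p] = X.T @ (w[:, None] * X)
        step = np.linalg.solve(H, score.T.reshape(-1))
        theta = theta + step.reshape(C - 1, p).T
        if np.max(np.abs(theta)) > 30:
            raise FitError(
                "separation suspected: coefficients diverging "
                f"(max |coef| = {np.max(np.abs(theta)):.1f})"
            )
    if not converged:
        probs = eta_probs(theta)
        resid = y[:, 1:] - m[:, None] * probs[:, 1:]
        raise FitError(
            f"no convergence after {max_iter} iterations; "
            f"last max |score| = {np.max(np.abs(X.T @ resid)):.3g}"
        )
    probs = eta_probs(theta)
    expected = probs * m[:, None]
    P = p * (C - 1)
    # per-group probabilities at the reference level of the other factors:
    # group dummies occupy columns 1..G-1 (group is the first factor)
    G = ct.n_groups
    Xg = np.zeros((G, p))
    Xg[:, 0] = 1.0
    Xg[1:, 1:G] = np.eye(G - 1)
    eta_g = np.concatenate([np.zeros((G, 1)), Xg @ theta], axis=1)
    pi_group = np.exp(eta_g - logsumexp(eta_g, axis=1, keepdims=True))
    return MultinomialFit(
        pi_hat=pi_group,
        beta=_beta_from_pi(pi_group),
        expected=expected,
        cluster_probs=probs,
        N=n * C,
        n=n,
        P=P,
        loglik=_multinomial_loglik(ct.counts, probs),
        converged=converged,
        n_iter=it,
        coef=theta,
    )


def _check_expected(expected: np.ndarray) -> None:
    if np.any(expected <= 1e-12):
        raise ZeroCellError(
            "fitted expected counts contain zeros; apply the zero-cell "
            "pseudo-observation adjustment (zero_adjust module) first"
        )


def pearson_stat(fit: MultinomialFit, ct: CountTable) -> float:
    """Pearson lack-of-fit statistic chi^2 = sum (y - mu)^2 / mu over all cells."""
    _check_expected(fit.expected)
    resid = ct.counts - fit.expected
    return float((resid**2 / fit.expected).sum())


def deviance_stat(fit: MultinomialFit, ct: CountTable) -> float:
    """Deviance D = 2 sum y log(y / mu), with 0 log(0/mu) = 0."""
    _check_expected(fit.expected)
    y = ct.counts
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(y > 0, y * np.log(y / fit.expected), 0.0)
    return float(2.0 * terms.sum())
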