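"""Dirichlet-multinomial data generation and the operating-characteristics harness.

Datasets are generated cluster by cluster: a probability vector is drawn from
Dirichlet(alpha * pi_g) and counts from a multinomial given that vector.  The
Dirichlet total alpha is chosen from the target dispersion phi and cluster
size m through phi = (m + alpha) / (1 + alpha), so the same synthetic data
satisfy both the quasi-multinomial (common phi) and the DM assumptions.

The harness replays the full analysis pipeline (optional zero-cell
adjustment, model fit, dispersion estimation, max-t adjustment) over many
replicates and reports the family-wise error rate, power and simultaneous
coverage with Monte-Carlo standard errors.  Every replicate's randomness is
derived deterministically from the master seed, scenario index and replicate
index, so studies are reproducible and parallel-safe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .contrasts import ContrastPair, dunnett_matrix, kronecker_map
from .dispersion import estimate_phi
from .dm_model import dm_theta, fit_dm
from .inference import (
    _correlation,
    assemble_V,
    max_t_probability,
    mvt_critical,
    sigma_g,
)
from .model_fit import CountTable, FitError, fit_multinomial
from .zero_adjust import add_pseudo, detect_zero_cells

__all__ = [
    "Scenario",
    "StudyResult",
    "alpha_from_phi",
    "simulate_dataset",
    "true_theta",
    "run_study",
    "default_null_scenario",
]

QUASI_METHODS = ("pearson", "deviance", "farrington", "afroz")
ALL_METHODS = ("plain",) + QUASI_METHODS + ("dm",)


def alpha_from_phi(phi: float, m: float) -> float:
    """Dirichlet total alpha giving dispersion phi at cluster size m.

    Inverts phi = (m + alpha) / (1 + alpha); requires 1 < phi < m since the
    DM dispersion is bounded by the cluster size.
    """
    if not 1.0 < phi < m:
        raise ValueError(
            f"phi must satisfy 1 < phi < m for DM generation, got phi={phi}, m={m}"
        )
    return (phi - m) / (1.0 - phi)


@dataclass
class Scenario:
    """True data-generating configuration for one simulation cell.

    ``phi`` may be a scalar (homogeneous dispersion) or one value per group;
    ``B_g`` a scalar or per-group cluster counts.  With
    ``variable_cluster_sizes`` the per-cluster totals are Poisson(m) draws
    truncated at 1 (the dispersion target is then interpreted at the mean
    cluster size).
    """

    pi: np.ndarray  # (G, C) true probability rows
    B_g: int | Sequence[int]
    m: int
    phi: float | Sequence[float]
    contrasts: ContrastPair
    variable_cluster_sizes: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if not np.allclose(self.pi.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("rows of pi must sum to 1")
        if np.any(self.pi <= 0):
            raise ValueError("true probabilities must be positive")
        G = self.pi.shape[0]
        self._B = np.full(G, self.B_g, dtype=int) if np.isscalar(self.B_g) else np.asarray(self.B_g, dtype=int)
        self._phi = np.full(G, self.phi, dtype=float) if np.isscalar(self.phi) else np.asarray(self.phi, dtype=float)
        if len(self._B) != G or len(self._phi) != G:
            raise ValueError("B_g and phi must be scalar or have one entry per group")
        if self.contrasts.G != G or self.contrasts.C != self.pi.shape[1]:
            raise ValueError("contrast dimensions do not match pi")

    @property
    def G(self) -> int:
        return self.pi.shape[0]

    @property
    def C(self) -> int:
        return self.pi.shape[1]

    @property
    def n_clusters(self) -> int:
        return int(self._B.sum())


def true_theta(sc: Scenario) -> tuple[np.ndarray, np.ndarray]:
    """True log odds ratios (B (x) A) . stacked log pi and their null flags."""
    M = kronecker_map(sc.contrasts)
    theta = M @ np.log(sc.pi).reshape(-1)
    return theta, np.abs(theta) < 1e-12


def simulate_dataset(sc: Scenario, seed=None) -> CountTable:
    """Draw one clustered dataset from the scenario's DM configuration.

    ``seed`` may be anything ``numpy.random.default_rng`` accepts, including
    an existing Generator.
    """
    rng = np.random.default_rng(seed)
    counts = []
    groups = []
    clusters = []
    for g in range(sc.G):
        alpha = alpha_from_phi(sc._phi[g], sc.m) * sc.pi[g]
        for b in range(sc._B[g]):
            m_gb = sc.m
            if sc.variable_cluster_sizes:
                m_gb = 0
                while m_gb < 1:  # Poisson truncated at 1: no empty clusters
                    m_gb = int(rng.poisson(sc.m))
            p = rng.dirichlet(alpha)
            counts.append(rng.multinomial(m_gb, p))
            groups.append(f"g{g+1}")
            clusters.append(f"g{g+1}b{b+1}")
    return CountTable(
        counts=np.array(counts),
        groups=np.array(groups),
        clusters=np.array(clusters),
        categories=[f"c{j+1}" for j in range(sc.C)],
        group_levels=[f"g{g+1}" for g in range(sc.G)],
    )


def default_null_scenario(
    G: int = 4,
    C: int = 3,
    B_g: int = 20,
    m: int = 50,
    phi: float = 5.0,
    pi_row: Sequence[float] | None = None,
) -> Scenario:
    """Global-null scenario with Dunnett-type contrasts on both margins."""
    row = np.full(C, 1.0 / C) if pi_row is None else np.asarray(pi_row, dtype=float)
    cp = ContrastPair(dunnett_matrix(C), dunnett_matrix(G))
    return Scenario(
        pi=np.tile(row, (G, 1)),
        B_g=B_g,
        m=m,
        phi=phi,
        contrasts=cp,
        name=f"null-G{G}C{C}B{B_g}m{m}phi{phi}",
    )


@dataclass
class StudyResult:
    """Long-format operating characteristics with Monte-Carlo uncertainty."""

    table: pd.DataFrame  # scenario, method, metric, estimate, mc_se, nsim, n_failed
    nsim: int
    seed: int
    alpha_level: float
    failures: dict = field(default_factory=dict)

    def estimate(self, scenario: str, method: str, metric: str) -> float:
        t = self.table
        row = t[(t.scenario == scenario) & (t.method == method) & (t.metric == metric)]
        if row.empty:
            raise KeyError((scenario, method, metric))
        return float(row.estimate.iloc[0])


def _rep_seed(master: int, scen_idx: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master, spawn_key=(scen_idx, rep))


def run_study(
    scenarios: Sequence[Scenario],
    methods: Sequence[str],
    nsim: int,
    alpha_level: float = 0.05,
    seed: int = 0,
    metrics: Sequence[str] = ("fwer", "power", "coverage"),
    zero_strategy: str = "none",
    dm_df: str = "residual",
    tol: float = 1e-4,
) -> StudyResult:
    """Monte-Carlo study of FWER, power and simultaneous coverage.

    For each scenario and replicate one dataset is drawn, optionally
    zero-adjusted, and every requested method is applied to the same data.
    FWER is the share of datasets with at least one rejected true null;
    power the proportion of false nulls correctly rejected (pooled over
    datasets and hypotheses); coverage the share of datasets whose
    simultaneous intervals contain every true log odds ratio.  Replicates
    where a method fails (non-convergence, unadjusted zero cells) are
    counted and excluded from that method's denominator.
    """
    methods = list(methods)
    if not methods:
        raise ValueError("at least one method is required")
    for meth in methods:
        if meth not in ALL_METHODS:
            raise ValueError(f"unknown method {meth!r}; choose from {ALL_METHODS}")
    metrics = tuple(metrics)
    rows = []
    failures: dict[tuple[str, str], int] = {}
    for s_idx, sc in enumerate(scenarios):
        name = sc.name or f"scenario{s_idx}"
        theta0, null_flags = true_theta(sc)
        false_idx = np.flatnonzero(~null_flags)
        need_crit = "coverage" in metrics or ("power" in metrics and len(false_idx) > 0)
        tallies = {
            meth: {"fwer": 0, "power_hits": 0, "power_tries": 0, "cover": 0, "n_ok": 0}
            for meth in methods
        }
        n_fail = {meth: 0 for meth in methods}
        for rep in range(nsim):
            ss = _rep_seed(seed, s_idx, rep)
            data_seed, adj_seed, mc_seed = ss.spawn(3)
            ct = simulate_dataset(sc, data_seed)
            if zero_strategy != "none" and detect_zero_cells(ct).zero_cells:
                strategy = (
                    "random_cluster" if zero_strategy == "random" else zero_strategy
                )
                ct, _ = add_pseudo(ct, strategy=strategy, seed=adj_seed)
            mc_rng_seed = mc_seed.generate_state(1)[0]
            base = _base_quantities(ct, sc.contrasts, methods)
            df_resid = base["df_resid"]
            q_quasi = None
            for meth in methods:
                try:
                    theta, se, t_stats, R, df_m = _method_stats(
                        meth, base, ct, sc.contrasts, dm_df
                    )
                except FitError:
                    n_fail[meth] += 1
                    continue
                tal = tallies[meth]
                tal["n_ok"] += 1
                if need_crit:
                    if meth != "dm" and q_quasi is not None:
                        q = q_quasi
                    else:
                        q = mvt_critical(
                            alpha_level, len(theta), df_m, R, seed=mc_rng_seed, tol=tol
                        )
                        if meth != "dm":
                            q_quasi = q
                    rej = np.abs(t_stats) > q
                    if "fwer" in metrics and null_flags.any():
                        tal["fwer"] += int(rej[null_flags].any())
                    if "power" in metrics and len(false_idx):
                        tal["power_hits"] += int(rej[false_idx].sum())
                        tal["power_tries"] += len(false_idx)
                    if "coverage" in metrics:
                        ok = np.all(np.abs(base_theta_diff(theta, theta0)) <= q * se)
                        tal["cover"] += int(ok)
                else:
                    # FWER only: one tail-probability call at the largest
                    # null statistic decides whether any true null is rejected
                    if null_flags.any():
                        t_max = float(np.max(np.abs(t_stats[null_flags])))
                        p_min = 1.0 - max_t_probability(
                            t_max, df_m, R, seed=mc_rng_seed, tol=tol
                        )
                        tal["fwer"] += int(p_min < alpha_level)
        for meth in methods:
            tal = tallies[meth]
            n_ok = tal["n_ok"]
            failures[(name, meth)] = n_fail[meth]
            if n_ok == 0:
                continue
            if "fwer" in metrics and null_flags.any():
                rows.append(_metric_row(name, meth, "fwer", tal["fwer"], n_ok, n_fail[meth]))
            if "power" in metrics and len(false_idx) and tal["power_tries"]:
                p = tal["power_hits"] / tal["power_tries"]
                rows.append(
                    dict(
                        scenario=name, method=meth, metric="power", estimate=p,
                        mc_se=float(np.sqrt(p * (1 - p) / tal["power_tries"])),
                        nsim=n_ok, n_failed=n_fail[meth],
                    )
                )
            if "coverage" in metrics and need_crit:
                rows.append(_metric_row(name, meth, "coverage", tal["cover"], n_ok, n_fail[meth]))
    return StudyResult(
        table=pd.DataFrame(
            rows,
            columns=["scenario", "method", "metric", "estimate", "mc_se", "nsim", "n_failed"],
        ),
        nsim=nsim,
        seed=seed,
        alpha_level=alpha_level,
        failures=failures,
    )


def base_theta_diff(theta_hat: np.ndarray, theta_true: np.ndarray) -> np.ndarray:
    return theta_hat - theta_true


def _metric_row(name: str, meth: str, metric: str, hits: int, n_ok: int, n_failed: int) -> dict:
    p = hits / n_ok
    return dict(
        scenario=name, method=meth, metric=metric, estimate=p,
        mc_se=float(np.sqrt(p * (1 - p) / n_ok)), nsim=n_ok, n_failed=n_failed,
    )


def _base_quantities(ct: CountTable, cp: ContrastPair, methods: Sequence[str]) -> dict:
    """Fit-once quantities shared by the plain and quasi methods."""
    base: dict = {}
    mfit = fit_multinomial(ct)
    base["mfit"] = mfit
    base["df_resid"] = mfit.df_residual
    if any(m != "dm" for m in methods):
        if np.any(mfit.pi_hat <= 0):
            base["quasi_error"] = FitError(
                "zero fitted probability (unadjusted zero cell)"
            )
        else:
            M = kronecker_map(cp)
            theta = M @ np.log(mfit.pi_hat).reshape(-1)
            group_m = np.zeros(ct.n_groups)
            np.add.at(group_m, ct.group_index, ct.cluster_totals)
            sigmas = [
                sigma_g(mfit.pi_hat[g], group_m[g], cp.A) for g in range(ct.n_groups)
            ]
            V1 = assemble_V(sigmas, cp.B, 1.0)
            base["theta"] = theta
            base["se1"] = np.sqrt(np.diag(V1))
            base["R"] = _correlation(V1)
    return base


def _method_stats(
    meth: str, base: dict, ct: CountTable, cp: ContrastPair, dm_df: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    if meth == "dm":
        dfit = fit_dm(ct)
        theta, V = dm_theta(dfit, cp)
        se = np.sqrt(np.diag(V))
        if np.any(se <= 0) or np.any(~np.isfinite(se)):
            raise FitError("non-positive DM standard errors")
        R = _correlation(V)
        df_m = np.inf if dm_df == "inf" else base["df_resid"]
        return theta, se, theta / se, R, df_m
    if "quasi_error" in base:
        raise base["quasi_error"]
    phi = 1.0
    if meth != "plain":
        phi = estimate_phi(base["mfit"], ct, meth).phi_hat
    se = base["se1"] * np.sqrt(phi)
    return base["theta"], se, base["theta"] / se, base["R"], base["df_resid"]
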