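"""Quasi-likelihood estimators of the multinomial dispersion parameter.

Overdispersion is modelled multiplicatively: Cov(y_gb) = phi * Sigma(y_gb)
with Sigma the multinomial covariance.  Four estimators of phi are provided,
all built on the residual degrees of freedom df = N - n - P (N = n*C cells,
n clusters, P non-redundant parameters):

* ``pearson``    — Wedderburn's chi^2 / df
* ``deviance``   — D / df
* ``farrington`` — (chi^2 - (N - n) * s_bar) / df
* ``afroz``      — (chi^2 / df) / (1 + s_bar)

where s_bar is the mean relative Pearson residual
s_gbc = (y_gbc - m_gb pi_gc) / (m_gb pi_gc), averaged over all N cells.
The Farrington and Afroz variants downweight the chi-square statistic's
sparse-data bias; Afroz is the least biased in simulation and is the
recommended default when strict error control matters.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .model_fit import CountTable, FitError, MultinomialFit, ZeroCellError, deviance_stat, pearson_stat

__all__ = ["DispersionEstimate", "estimate_phi", "scaled_covariance", "METHODS"]

METHODS = ("pearson", "deviance", "farrington", "afroz")

_PHI_FLOOR = 1e-6


@dataclass
class DispersionEstimate:
    """phi_hat with the lack-of-fit intermediates it was built from."""

    method: str
    phi_hat: float
    chi2: float
    D: float
    s_bar: float
    df: int


def _s_bar(fit: MultinomialFit, ct: CountTable) -> float:
    resid = (ct.counts - fit.expected) / fit.expected
    s = float(resid.mean())
    if not np.isfinite(s):
        raise ZeroCellError("non-finite mean relative residual (zero expected count)")
    return s


def estimate_phi(fit: MultinomialFit, ct: CountTable, method: str = "afroz") -> DispersionEstimate:
    """Estimate the dispersion parameter phi by the named estimator.

    Requires df = N - n - P >= 1 and strictly positive expected counts.
    A Farrington estimate that falls below zero (extreme negative s_bar)
    is floored at 1e-6 with a warning; no ceiling or floor at 1 is applied
    otherwise, since quasi-likelihood admits underdispersion.
    """
    if method not in METHODS:
        raise ValueError(f"unknown dispersion method {method!r}; choose from {METHODS}")
    df = fit.df_residual
    if df < 1:
        raise FitError(
            f"saturated model: residual df = {df} (N={fit.N}, n={fit.n}, P={fit.P})"
        )
    chi2 = pearson_stat(fit, ct)
    D = deviance_stat(fit, ct)
    s_bar = _s_bar(fit, ct)
    if method == "pearson":
        phi = chi2 / df
    elif method == "deviance":
        phi = D / df
    elif method == "farrington":
        phi = (chi2 - (fit.N - fit.n) * s_bar) / df
        if phi <= 0:
            warnings.warn(
                f"Farrington dispersion estimate {phi:.3g} <= 0; floored at {_PHI_FLOOR}",
                stacklevel=2,
            )
            phi = _PHI_FLOOR
    else:  # afroz
        phi = (chi2 / df) / (1.0 + s_bar)
    return DispersionEstimate(method=method, phi_hat=float(phi), chi2=chi2, D=D, s_bar=s_bar, df=df)


def estimate_all(fit: MultinomialFit, ct: CountTable) -> dict[str, DispersionEstimate]:
    """All four dispersion estimates on the same fit (shared intermediates)."""
    return {m: estimate_phi(fit, ct, m) for m in METHODS}


def scaled_covariance(sigma: np.ndarray, phi: float) -> np.ndarray:
    """Inflate a model covariance by the dispersion factor (SEs scale by sqrt(phi))."""
    if phi <= 0:
        raise ValueError(f"phi must be positive, got {phi}")
    return np.asarray(sigma, dtype=float) * phi
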