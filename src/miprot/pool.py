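"""Per-draw linear-model fits, Rubin's-rules pooling and variance projection.

Each completed dataset is fitted analyte-by-analyte with ordinary least
squares under cell-means coding (one indicator column per condition), so
the coefficients are the condition means and X'X = diag(n_k).  The D fits
are pooled with Rubin's rules:

* combined coefficients: the mean over draws;
* combined covariance: mean within-imputation covariance plus the
  between-imputation outer-product term scaled by (D+1)/(D(D-1)).

Because downstream testing needs a scalar variance, the pooled K x K
covariance is projected to ``s_p = max_k Sigma_{p,(k,k)} * n_k`` — each
coefficient's pooled variance rescaled to residual-variance scale by its
sample count, maximised over conditions.  On complete data all draws agree,
the between-term vanishes, and the projection returns exactly the OLS
residual variance, so the whole stage collapses to a single classical fit.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .impute import ImputationEnsemble
from .quant import ExperimentDesign

__all__ = [
    "PerImputationFit",
    "PooledFit",
    "fit_per_imputation",
    "rubin_combine",
    "project_variance",
    "pool_ensemble",
]


@dataclass
class PerImputationFit:
    """OLS results for every analyte in every completed dataset.

    coef has shape (D, P, K) — condition means; sigma2 has shape (D, P) —
    unbiased residual variances; the within-imputation covariance of the
    coefficient vector is W_d = sigma2 * (X'X)^{-1} = diag(sigma2 / n_k).
    """

    coef: np.ndarray
    sigma2: np.ndarray
    dof: int
    design: ExperimentDesign

    @property
    def n_draws(self) -> int:
        return self.coef.shape[0]


@dataclass
class PooledFit:
    """Rubin-pooled per-analyte estimates.

    coef: (P, K) combined coefficients; cov: (P, K, K) pooled covariance;
    s2: (P,) projected scalar variance on residual-variance scale; dof:
    residual degrees of freedom N - K (common to all analytes).
    """

    coef: np.ndarray
    cov: np.ndarray
    s2: np.ndarray
    dof: int
    design: ExperimentDesign
    within_cov: np.ndarray | None = None


def fit_per_imputation(
    ensemble: ImputationEnsemble | np.ndarray, design: ExperimentDesign
) -> PerImputationFit:
    """Cell-means OLS per analyte per draw, fully vectorised.

    Under cell-means coding the coefficient estimates are the per-condition
    sample means and the unbiased residual variance is the pooled
    within-condition sum of squares over N - K.
    """
    data = ensemble.data if isinstance(ensemble, ImputationEnsemble) else np.asarray(ensemble)
    if data.ndim == 2:
        data = data[None]
    D, P, N = data.shape
    if N != design.N:
        raise ValueError("design does not match ensemble sample count")
    K = design.K
    dof = N - K
    if dof < 1:
        raise ValueError("need N - K >= 1 residual degrees of freedom")
    X = design.X  # N x K indicators
    n_k = design.n_k.astype(float)
    coef = data @ X / n_k  # (D, P, K): condition means
    fitted = coef @ X.T
    resid = data - fitted
    sigma2 = (resid**2).sum(axis=2) / dof
    return PerImputationFit(coef=coef, sigma2=sigma2, dof=dof, design=design)


def rubin_combine(fits: PerImputationFit) -> PooledFit:
    """Pool per-draw fits with Rubin's rules.

    The combined covariance is ``mean_d(W_d) + (D+1)/(D(D-1)) *
    sum_d (b_d - b)'(b_d - b)``; with a single draw the between-term is
    defined as zero (flagged with a warning) to support the
    single-imputation baseline.
    """
    D, P, K = fits.coef.shape
    coef = fits.coef.mean(axis=0)  # (P, K)
    inv_nk = 1.0 / fits.design.n_k.astype(float)
    within = np.einsum("dp,kj->pkj", fits.sigma2 / D, np.diag(inv_nk))
    if D >= 2:
        dev = fits.coef - coef  # (D, P, K)
        between = np.einsum("dpk,dpj->pkj", dev, dev)
        cov = within + (D + 1.0) / (D * (D - 1.0)) * between
    else:
        warnings.warn("single-draw pooling: between-imputation term set to 0")
        cov = within
    pooled = PooledFit(
        coef=coef,
        cov=cov,
        s2=np.empty(P),
        dof=fits.dof,
        design=fits.design,
        within_cov=within,
    )
    pooled.s2 = project_variance(pooled, fits.design)
    return pooled


def project_variance(pooled: PooledFit, design: ExperimentDesign) -> np.ndarray:
    """Project each pooled covariance to a scalar on residual-variance scale.

    ``s_p = max_k Sigma_{p,(k,k)} * (X'X)_{kk}``.  Requires cell-means
    coding (diagonal X'X); the per-condition rescaling undoes the 1/n_k of
    the coefficient variance so that, absent between-imputation spread,
    the result is exactly the OLS residual variance.
    """
    XtX = design.X.T @ design.X
    if not np.allclose(XtX, np.diag(np.diag(XtX))):
        raise ValueError("X'X is not diagonal; use cell-means condition coding")
    diag = np.einsum("pkk->pk", pooled.cov)
    return (diag * np.diag(XtX)).max(axis=1)


def pool_ensemble(ensemble: ImputationEnsemble, design: ExperimentDesign) -> PooledFit:
    """Convenience: per-draw OLS then Rubin pooling and projection."""
    return rubin_combine(fit_per_imputation(ensemble, design))
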