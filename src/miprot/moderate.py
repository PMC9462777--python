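"""Empirical-Bayes variance moderation and moderated t-testing.

The projected per-analyte variances s_p^2 (residual-variance scale, dof
d_p) are assumed to follow the conjugate hierarchy

    s_p^2 | sigma_p^2  ~  sigma_p^2 * chi2_{d_p} / d_p
    1 / sigma_p^2      ~  chi2_{d_0} / (d_0 * s_0^2)

whose hyperparameters (d_0, s_0^2) are estimated across analytes by moment
matching on log variances (the classic limma procedure: the excess spread
of log s_p^2 over its chi-square sampling component identifies d_0 through
the trigamma function).  The posterior-mean variance

    s^2_mod = (d_p s_p^2 + d_0 s_0^2) / (d_p + d_0)

replaces the sample variance in the t-statistic, which under the null is
Student with d_p + d_0 degrees of freedom (Gaussian when d_0 is infinite).
Benjamini-Hochberg step-up adjustment controls the false discovery rate
across analytes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .pool import PooledFit
from .quant import ExperimentDesign

__all__ = [
    "ModerationPrior",
    "estimate_prior",
    "moderate_variance",
    "moderated_t",
    "adjust_bh",
    "trigamma_inverse",
]


@dataclass
class ModerationPrior:
    """Scaled-inverse-chi-square prior: d0 degrees of freedom, s0^2 scale."""

    d0: float
    s02: float

    def __post_init__(self):
        if not self.d0 > 0:
            raise ValueError("d0 must be > 0")
        if not self.s02 > 0:
            raise ValueError("s0^2 must be > 0")


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, dof: float | np.ndarray) -> ModerationPrior:
    """Estimate (d0, s0^2) by moment matching on log variances.

    Exact-zero variances (constant rows) are excluded with a warning, since
    the hierarchy requires positive scales.  If the log variances show no
    excess spread beyond their chi-square sampling variability the prior is
    degenerate: d0 = +inf and s0^2 is the corrected mean scale (the common
    value when all variances are equal).
    """
    s2 = np.asarray(s2, dtype=float)
    dof = np.broadcast_to(np.asarray(dof, dtype=float), s2.shape)
    ok = s2 > 0
    if (~ok).any():
        warnings.warn(f"excluding {int((~ok).sum())} non-positive variances from prior fit")
    s2, dof = s2[ok], dof[ok]
    n = s2.size
    if n < 2:
        raise ValueError("need at least two positive variances to fit the prior")

    z = np.log(s2)
    e = z - special.digamma(dof / 2.0) + np.log(dof / 2.0)
    emean = e.mean()
    if np.allclose(z, z[0]):
        # zero spread: infinitely concentrated prior at the common value
        return ModerationPrior(d0=np.inf, s02=float(np.exp(z[0])))
    evar = float(np.mean(n / (n - 1.0) * (e - emean) ** 2 - special.polygamma(1, dof / 2.0)))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return ModerationPrior(d0=d0, s02=s02)


def moderate_variance(s2, prior: ModerationPrior, dof) -> np.ndarray:
    """Posterior-mean variance: (d_p s^2 + d0 s0^2) / (d_p + d0)."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(prior.d0):
        return np.full_like(s2, prior.s02)
    return (dof * s2 + prior.d0 * prior.s02) / (dof + prior.d0)


def moderated_t(
    pooled: PooledFit,
    s2_mod: np.ndarray,
    contrast: np.ndarray,
    design: ExperimentDesign,
    prior: ModerationPrior,
) -> pd.DataFrame:
    """Moderated t-test of c'beta = 0 with the moderated variance.

    T = c'beta / sqrt(s2_mod * c'(X'X)^{-1}c); two-sided p-values from the
    Student distribution with d_p + d0 degrees of freedom (Gaussian when
    d0 is infinite).
    """
    c = np.asarray(contrast, dtype=float)
    if c.shape != (design.K,) or not c.any():
        raise ValueError("contrast must be a nonzero K-vector")
    estimate = pooled.coef @ c
    scale = float(c @ np.diag(1.0 / design.n_k.astype(float)) @ c)
    var = s2_mod * scale
    df = pooled.dof + prior.d0
    t = np.zeros_like(estimate)
    p = np.ones_like(estimate)
    pos = var > 0
    t[pos] = estimate[pos] / np.sqrt(var[pos])
    if np.isinf(df):
        p[pos] = 2.0 * stats.norm.sf(np.abs(t[pos]))
    else:
        p[pos] = 2.0 * stats.t.sf(np.abs(t[pos]), df)
    degenerate = ~pos & (estimate != 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} analytes have zero moderated variance with "
            "nonzero estimate; p set to 0"
        )
        t[degenerate] = np.inf * np.sign(estimate[degenerate])
        p[degenerate] = 0.0
    return pd.DataFrame(
        {
            "estimate": estimate,
            "s2": pooled.s2,
            "s2_moderated": s2_mod,
            "t": t,
            "df": df,
            "p_value": p,
        }
    )


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs propagate)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        if ((p[ok] < 0) | (p[ok] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
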