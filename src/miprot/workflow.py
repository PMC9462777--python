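"""End-to-end differential-analysis workflows.

``PooledModeratedTTest`` is the multiple-imputation arm: impute D times,
fit the cell-means linear model per draw, pool with Rubin's rules, project
the pooled covariance to a scalar variance, moderate it with the
empirical-Bayes prior and test each pairwise condition contrast with the
moderated t-statistic, BH-adjusting p-values per contrast.

``SingleImputationModeratedTTest`` is the single-imputation baseline: one
draw of the same engine, ordinary per-analyte OLS residual variances,
the same moderation and testing.  On complete data the two arms are
identical, because every draw of an ensemble equals the source and the
between-imputation term vanishes.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .impute import multi_impute
from .moderate import adjust_bh, estimate_prior, moderate_variance, moderated_t
from .pool import fit_per_imputation, rubin_combine
from .quant import QuantTable

__all__ = [
    "PooledModeratedTTest",
    "SingleImputationModeratedTTest",
    "run_mi_workflow",
    "run_baseline_workflow",
]


class PooledModeratedTTest(BaseEstimator):
    """Multiple-imputation moderated t-test workflow.

    Parameters
    ----------
    method : {"knn", "mle", "norm", "pca", "rf"}
        Imputation engine.
    n_draws : int or None
        Number of imputation draws; ``None`` applies the draw rule.
    scope : {"condition", "global"} or None
        Imputation scope; ``None`` uses the engine default.
    alpha : float
        BH-adjusted significance threshold for the ``significant`` column.
    random_state : int or None
        Master seed for the imputation draws.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per analyte and contrast: estimate, projected variance,
        moderated variance, t, dof, raw and BH-adjusted p, decision.
    prior_ : ModerationPrior
    pooled_ : PooledFit
    ensemble_ : ImputationEnsemble
    """

    _min_draws = None  # subclass hook

    def __init__(
        self,
        method: str = "mle",
        n_draws: int | None = None,
        scope: str | None = None,
        alpha: float = 0.05,
        random_state: int | None = None,
        engine_params: dict | None = None,
    ):
        self.method = method
        self.n_draws = n_draws
        self.scope = scope
        self.alpha = alpha
        self.random_state = random_state
        self.engine_params = engine_params

    def _ensemble(self, table: QuantTable):
        return multi_impute(
            table,
            method=self.method,
            D=self.n_draws,
            scope=self.scope,
            seed=self.random_state,
            **(self.engine_params or {}),
        )

    def fit(self, table: QuantTable, y=None):
        design = table.design()
        self.ensemble_ = self._ensemble(table)
        fits = fit_per_imputation(self.ensemble_, design)
        self.pooled_ = rubin_combine(fits)
        self.prior_ = estimate_prior(self.pooled_.s2, self.pooled_.dof)
        s2_mod = moderate_variance(self.pooled_.s2, self.prior_, self.pooled_.dof)
        frames = []
        for name, c in design.pairwise_contrasts():
            res = moderated_t(self.pooled_, s2_mod, c, design, self.prior_)
            res.insert(0, "contrast", name)
            res.insert(0, "analyte_id", table.analyte_ids)
            res["p_adjusted"] = adjust_bh(res["p_value"].to_numpy())
            res["significant"] = res["p_adjusted"] <= self.alpha
            frames.append(res)
        self.results_ = pd.concat(frames, ignore_index=True)
        self.design_ = design
        return self

    def fit_predict(self, table: QuantTable) -> np.ndarray:
        """Fit and return the boolean decision vector (first contrast)."""
        self.fit(table)
        first = self.results_["contrast"] == self.results_["contrast"].iloc[0]
        return self.results_.loc[first, "significant"].to_numpy()


class SingleImputationModeratedTTest(PooledModeratedTTest):
    """Single-imputation baseline: one draw, ordinary residual variances.

    The between-imputation term never enters (D = 1 by construction); the
    projected variance is exactly the OLS residual variance, which is then
    moderated and tested as in the multiple-imputation arm.
    """

    def _ensemble(self, table: QuantTable):
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="single-draw")
            return multi_impute(
                table,
                method=self.method,
                D=1,
                scope=self.scope,
                seed=self.random_state,
                **(self.engine_params or {}),
            )

    def fit(self, table: QuantTable, y=None):
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="single-draw")
            return super().fit(table)


def run_mi_workflow(
    table: QuantTable,
    method: str = "mle",
    D: int | None = None,
    alpha: float = 0.05,
    seed: int | None = None,
    scope: str | None = None,
    **engine_params,
) -> pd.DataFrame:
    """Multiple-imputation workflow; returns the per-analyte result table."""
    est = PooledModeratedTTest(
        method=method,
        n_draws=D,
        scope=scope,
        alpha=alpha,
        random_state=seed,
        engine_params=engine_params or None,
    )
    return est.fit(table).results_


def run_baseline_workflow(
    table: QuantTable,
    method: str = "mle",
    alpha: float = 0.05,
    seed: int | None = None,
    scope: str | None = None,
    **engine_params,
) -> pd.DataFrame:
    """Single-imputation baseline; returns the per-analyte result table."""
    est = SingleImputationModeratedTTest(
        method=method,
        scope=scope,
        alpha=alpha,
        random_state=seed,
        engine_params=engine_params or None,
    )
    return est.fit(table).results_
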