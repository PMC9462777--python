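"""Stochastic imputation engines and the multiple-imputation orchestrator.

Five engines complete an analytes x samples matrix with missing cells:

* ``EMGaussianImputer`` ("mle") — fits a multivariate Gaussian over the
  sample columns by expectation-maximisation, then draws each missing cell
  from the conditional predictive distribution given the row's observed
  cells.
* ``KNNBootstrapImputer`` ("knn") — mean of the k nearest donor rows by
  (nan-)Euclidean distance; between-draw variability comes from
  bootstrap-resampling the donor rows.
* ``ChainedNormImputer`` ("norm") — chained-equations Bayesian linear
  regression: cycle over columns, draw regression coefficients and noise
  scale from their conjugate posterior, impute.  Applied globally.
* ``IterativePCAImputer`` ("pca") — iterative low-rank reconstruction, plus
  Gaussian residual noise on the imputed cells so draws differ.
* ``RandomForestImputer`` ("rf") — missForest-style iterative column-wise
  random-forest regression.

``multi_impute`` repeats the chosen engine D times (D from the draw rule:
the ceiling of the percentage of missing values, floored at 2) to build an
:class:`ImputationEnsemble`.  Engines other than "norm" are applied per
experimental condition by default; "norm" is global.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.impute import KNNImputer as _SKKNNImputer

from .quant import QuantTable

logger = logging.getLogger(__name__)

__all__ = [
    "ConvergenceError",
    "ImputationEnsemble",
    "choose_num_draws",
    "EMGaussianImputer",
    "KNNBootstrapImputer",
    "ChainedNormImputer",
    "IterativePCAImputer",
    "RandomForestImputer",
    "MultipleImputer",
    "multi_impute",
    "impute_knn",
    "impute_mle",
    "impute_norm",
    "impute_pca",
    "impute_rf",
    "ENGINES",
    "DEFAULT_SCOPE",
]


class ConvergenceError(RuntimeError):
    """Raised when an iterative imputation engine fails to converge."""

    def __init__(self, message: str, n_iter: int):
        super().__init__(f"{message} (after {n_iter} iterations)")
        self.n_iter = n_iter


def choose_num_draws(missing_proportion: float) -> int:
    """Number of imputation draws: ceiling of the missing percentage, min 2."""
    if not 0 <= missing_proportion < 1:
        raise ValueError("missing proportion must be in [0, 1)")
    if missing_proportion < 0.01:
        return 2
    return max(2, math.ceil(100.0 * missing_proportion))


@dataclass
class ImputationEnsemble:
    """D completed copies of a quantification table plus provenance.

    ``data`` has shape (D, P, N); cells observed in the source are identical
    across draws and equal to the source.
    """

    data: np.ndarray
    source: QuantTable
    method: str
    scope: str
    seed: int | None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ensemble data must be D x P x N")
        if self.data.shape[1:] != self.source.values.shape:
            raise ValueError("ensemble shape does not match source table")
        if np.isnan(self.data).any():
            raise ValueError("completed matrices must be finite everywhere")
        obs = ~self.source.mask
        if not np.array_equal(
            np.broadcast_to(self.source.values[obs], (self.n_draws, obs.sum())),
            self.data[:, obs],
        ):
            raise ValueError("observed cells altered by imputation")
        if self.n_draws == 1:
            warnings.warn(
                "single-draw ensemble: between-imputation variance is zero",
                stacklevel=2,
            )

    @property
    def n_draws(self) -> int:
        return self.data.shape[0]

    @property
    def source_mask(self) -> np.ndarray:
        return self.source.mask


# ---------------------------------------------------------------------------
# EM Gaussian ("mle")
# ---------------------------------------------------------------------------

class EMGaussianImputer(BaseEstimator):
    """Multivariate-Gaussian imputation fitted by expectation-maximisation.

    Rows of the matrix are treated as i.i.d. observations of an
    N(mu, Sigma) vector over the sample columns.  ``fit`` estimates
    (mu, Sigma) from the incomplete rows; ``sample`` draws every missing
    cell from the conditional predictive distribution given the row's
    observed cells, so repeated draws differ.  ``transform`` fills with the
    conditional mean (deterministic).

    Parameters
    ----------
    max_iter : int
        EM iteration cap; exceeding it raises :class:`ConvergenceError`.
    tol : float
        Relative log-likelihood change at which EM stops.
    ridge : float
        Relative ridge (times trace/dim) added when the covariance turns
        singular, with a warning.
    """

    def __init__(self, max_iter: int = 500, tol: float = 1e-6, ridge: float = 1e-6):
        self.max_iter = max_iter
        self.tol = tol
        self.ridge = ridge

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        mask = np.isnan(X)
        n = X.shape[1]
        rows = ~mask.all(axis=1)  # fully-missing rows carry no information
        Xf, Mf = X[rows], mask[rows]
        if Xf.shape[0] < 2:
            raise ValueError("EM needs at least two partially observed rows")

        mu = np.nanmean(Xf, axis=0)
        filled = np.where(Mf, mu, Xf)
        sigma = np.cov(filled, rowvar=False, bias=True)
        sigma = np.atleast_2d(sigma) + 1e-8 * np.eye(n)

        patterns = _group_patterns(Mf)
        last_ll = None
        for it in range(1, self.max_iter + 1):
            mu, sigma, ll = self._em_step(Xf, patterns, mu, sigma)
            if last_ll is not None and abs(ll - last_ll) <= self.tol * (abs(last_ll) + 1e-12):
                self.n_iter_, self.converged_ = it, True
                break
            last_ll = ll
        else:
            raise ConvergenceError("EM did not converge", self.max_iter)
        self.mean_, self.cov_, self.loglik_ = mu, sigma, ll
        return self

    def _em_step(self, X, patterns, mu, sigma):
        m, n = X.shape
        sum_x = np.zeros(n)
        sum_xx = np.zeros((n, n))
        ll = 0.0
        for key, (rows, obs, mis) in patterns.items():
            Xo = X[np.ix_(rows, obs)]
            g = len(rows)
            Soo = sigma[np.ix_(obs, obs)]
            try:
                L = np.linalg.cholesky(Soo)
            except np.linalg.LinAlgError:
                Soo = Soo + self.ridge * (np.trace(Soo) / len(obs) + 1e-12) * np.eye(len(obs))
                warnings.warn("singular observed-block covariance; ridge added")
                L = np.linalg.cholesky(Soo)
            dev = Xo - mu[obs]
            sol = np.linalg.solve(L, dev.T)  # len(obs) x g
            ll += -0.5 * (
                g * (len(obs) * np.log(2 * np.pi) + 2 * np.log(np.diag(L)).sum())
                + (sol**2).sum()
            )
            full = np.empty((g, n))
            full[:, obs] = Xo
            if len(mis):
                K = np.linalg.solve(L.T, np.linalg.solve(L, sigma[np.ix_(obs, mis)]))
                cond_mean = mu[mis] + dev @ K
                C = sigma[np.ix_(mis, mis)] - sigma[np.ix_(mis, obs)] @ K
                full[:, mis] = cond_mean
                sum_xx[np.ix_(mis, mis)] += g * C
            sum_x += full.sum(axis=0)
            sum_xx += full.T @ full
        mu_new = sum_x / m
        sigma_new = sum_xx / m - np.outer(mu_new, mu_new)
        sigma_new = 0.5 * (sigma_new + sigma_new.T)
        return mu_new, sigma_new, ll

    def _conditional(self, x_obs_dev, obs, mis):
        """Conditional mean offset and covariance of ``mis`` given ``obs``."""
        Soo = self.cov_[np.ix_(obs, obs)]
        K = np.linalg.solve(Soo, self.cov_[np.ix_(obs, mis)])
        mean = self.mean_[mis] + x_obs_dev @ K
        C = self.cov_[np.ix_(mis, mis)] - self.cov_[np.ix_(mis, obs)] @ K
        return mean, 0.5 * (C + C.T)

    def _complete(self, X, rng):
        X = np.asarray(X, dtype=float)
        mask = np.isnan(X)
        out = X.copy()
        for key, (rows, obs, mis) in _group_patterns(mask).items():
            if not len(mis):
                continue
            if len(obs):
                mean, C = self._conditional(X[np.ix_(rows, obs)] - self.mean_[obs], obs, mis)
            else:
                mean = np.broadcast_to(self.mean_[mis], (len(rows), len(mis)))
                C = self.cov_[np.ix_(mis, mis)]
            if rng is None:
                out[np.ix_(rows, mis)] = mean
            else:
                jitter = 1e-10 * (np.trace(C) / max(len(mis), 1) + 1e-12)
                L = np.linalg.cholesky(C + jitter * np.eye(len(mis)))
                z = rng.standard_normal((len(rows), len(mis)))
                out[np.ix_(rows, mis)] = mean + z @ L.T
        return out

    def sample(self, X, rng):
        """Draw one completed matrix from the conditional predictive."""
        return self._complete(X, np.random.default_rng(rng))

    def transform(self, X):
        """Deterministic completion with the conditional mean."""
        return self._complete(X, None)


def _group_patterns(mask: np.ndarray):
    """Group row indices by missingness pattern: key -> (rows, obs, mis)."""
    out = {}
    keys = np.packbits(mask, axis=1).tobytes() if mask.size else b""
    width = (mask.shape[1] + 7) // 8
    for i in range(mask.shape[0]):
        key = keys[i * width : (i + 1) * width]
        out.setdefault(key, []).append(i)
    grouped = {}
    for key, rows in out.items():
        m = mask[rows[0]]
        grouped[key] = (
            np.asarray(rows),
            np.flatnonzero(~m),
            np.flatnonzero(m),
        )
    return grouped


# ---------------------------------------------------------------------------
# k-nearest neighbours ("knn")
# ---------------------------------------------------------------------------

class KNNBootstrapImputer(BaseEstimator):
    """Neighbour-mean imputation with bootstrap donor resampling.

    Each missing cell is the mean of the ``n_neighbors`` nearest donor rows
    (Euclidean distance over mutually observed columns, via scikit-learn's
    nan-Euclidean metric).  Plain kNN is deterministic; to obtain
    between-imputation variability, each draw bootstrap-resamples the donor
    rows.  Rows missing more than ``row_missing_fallback`` of their cells
    fall back to row-mean imputation.
    """

    def __init__(
        self,
        n_neighbors: int = 10,
        bootstrap: bool = True,
        row_missing_fallback: float = 0.5,
    ):
        self.n_neighbors = n_neighbors
        self.bootstrap = bootstrap
        self.row_missing_fallback = row_missing_fallback

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        usable = (~np.isnan(X)).any(axis=1).sum()
        if self.n_neighbors > usable:
            raise ValueError(
                f"n_neighbors={self.n_neighbors} exceeds the {usable} usable donor rows"
            )
        self.X_fit_ = X
        return self

    def sample(self, X, rng):
        rng = np.random.default_rng(rng)
        X = np.asarray(X, dtype=float)
        mask = np.isnan(X)
        out = X.copy()
        if not mask.any():
            return out
        donors = self.X_fit_
        if self.bootstrap:
            for _ in range(20):
                idx = rng.integers(0, donors.shape[0], size=donors.shape[0])
                cand = self.X_fit_[idx]
                if not np.isnan(cand).all(axis=0).any():
                    donors = cand
                    break
        sk = _SKKNNImputer(n_neighbors=min(self.n_neighbors, donors.shape[0]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sk.fit(donors)
            filled = sk.transform(X)
        out[mask] = filled[mask]
        # heavily missing rows: fall back to the row's observed mean
        frac = mask.mean(axis=1)
        for i in np.flatnonzero(frac > self.row_missing_fallback):
            obs = ~mask[i]
            if obs.any():
                out[i, mask[i]] = X[i, obs].mean()
                logger.warning(
                    "row %d has %.0f%% missing cells; row-mean fallback used",
                    i,
                    100 * frac[i],
                )
        return out

    def transform(self, X):
        """Deterministic kNN completion (no bootstrap)."""
        saved, self.bootstrap = self.bootstrap, False
        try:
            return self.sample(X, 0)
        finally:
            self.bootstrap = saved


# ---------------------------------------------------------------------------
# Chained-equations Bayesian regression ("norm")
# ---------------------------------------------------------------------------

class ChainedNormImputer(BaseEstimator):
    """Chained-equations imputation under the normal model.

    Cycles over columns in input order; each incomplete column is regressed
    on all the others (current completions), the noise variance is drawn
    from its scaled inverse-chi-square posterior and the coefficients from
    their conditional Gaussian posterior, and the missing entries are
    imputed from the posterior predictive.  A small relative ridge
    stabilises near-collinear predictors.  Applied to the full matrix
    (global scope).
    """

    def __init__(self, n_cycles: int = 10, ridge: float = 1e-5):
        self.n_cycles = n_cycles
        self.ridge = ridge

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[1] < 2:
            raise ValueError("chained-equations imputation needs >= 2 columns")
        return self

    def sample(self, X, rng):
        rng = np.random.default_rng(rng)
        X = np.asarray(X, dtype=float)
        mask = np.isnan(X)
        out = X.copy()
        if not mask.any():
            return out
        col_means = np.nanmean(X, axis=0)
        out[mask] = np.broadcast_to(col_means, X.shape)[mask]
        todo = np.flatnonzero(mask.any(axis=0))
        for _ in range(self.n_cycles):
            for j in todo:
                obs, mis = ~mask[:, j], mask[:, j]
                others = np.delete(np.arange(X.shape[1]), j)
                Z = np.column_stack([np.ones(X.shape[0]), out[:, others]])
                y = X[obs, j]
                out[mis, j] = self._norm_draw(Z[obs], y, Z[mis], rng)
        return out

    def _norm_draw(self, Zo, y, Zm, rng):
        q = Zo.shape[1]
        S = Zo.T @ Zo
        V = np.linalg.inv(S + self.ridge * np.diag(np.diag(S)) + 1e-10 * np.eye(q))
        beta_hat = V @ Zo.T @ y
        resid = y - Zo @ beta_hat
        df = max(len(y) - q, 1)
        sigma2 = float(resid @ resid) / rng.chisquare(df)
        L = np.linalg.cholesky(sigma2 * (V + V.T) / 2.0 + 1e-12 * np.eye(q))
        beta_star = beta_hat + L @ rng.standard_normal(q)
        return Zm @ beta_star + rng.normal(0.0, math.sqrt(sigma2), size=Zm.shape[0])


# ---------------------------------------------------------------------------
# Iterative PCA ("pca")
# ---------------------------------------------------------------------------

class IterativePCAImputer(BaseEstimator):
    """Iterative low-rank reconstruction of missing cells.

    Missing cells start at column means; each iteration centres the
    current completion, reconstructs it at rank ``n_components`` by SVD and
    updates the missing cells, until the relative change falls below
    ``tol``.  With ``noise`` on (the default), Gaussian noise with the
    residual RMSE is added to the imputed cells so draws differ.
    """

    def __init__(
        self,
        n_components: int = 2,
        max_iter: int = 5000,
        tol: float = 1e-5,
        noise: bool = True,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.noise = noise

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.n_components >= min(X.shape):
            raise ValueError("n_components must be < min(n_rows, n_cols)")
        return self

    def sample(self, X, rng):
        rng = np.random.default_rng(rng)
        X = np.asarray(X, dtype=float)
        mask = np.isnan(X)
        out = X.copy()
        if not mask.any():
            return out
        out[mask] = np.broadcast_to(np.nanmean(X, axis=0), X.shape)[mask]
        recon = out
        obs = ~mask
        m = math.sqrt(float(mask.sum()))
        for it in range(1, self.max_iter + 1):
            mu = out.mean(axis=0)
            U, s, Vt = np.linalg.svd(out - mu, full_matrices=False)
            r = self.n_components
            recon = (U[:, :r] * s[:r]) @ Vt[:r] + mu
            delta = math.sqrt(float(((recon[mask] - out[mask]) ** 2).sum()))
            scale = math.sqrt(float((out[mask] ** 2).sum())) + 1e-12
            out[mask] = recon[mask]
            if delta <= self.tol * scale:
                break
            # refinement far below the residual noise level is immaterial:
            # the per-draw noise added afterwards has sd = residual RMSE
            rmse_cur = math.sqrt(float(np.mean((recon[obs] - X[obs]) ** 2)))
            if it > 1 and delta / m <= 1e-3 * rmse_cur:
                break
        else:
            raise ConvergenceError("iterative PCA did not converge", self.max_iter)
        self.n_iter_ = it
        obs = ~mask
        rmse = math.sqrt(float(np.mean((recon[obs] - X[obs]) ** 2)))
        self.residual_rmse_ = rmse
        if self.noise and rmse > 0:
            out[mask] += rng.normal(0.0, rmse, size=int(mask.sum()))
        return out

    def transform(self, X):
        saved, self.noise = self.noise, False
        try:
            return self.sample(X, 0)
        finally:
            self.noise = saved


# ---------------------------------------------------------------------------
# Random forest ("rf")
# ---------------------------------------------------------------------------

class RandomForestImputer(BaseEstimator):
    """missForest-style iterative column-wise random-forest imputation.

    Each incomplete column is regressed on the others with a random forest
    and its missing entries replaced by the forest's predictions; sweeps
    repeat until the normalised change between iterations stops decreasing
    (the previous completion is then returned).  Between-draw stochasticity
    comes from the forest's bootstrap/tree seeds.
    """

    def __init__(self, n_estimators: int = 100, max_iter: int = 10):
        self.n_estimators = n_estimators
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[1] < 2:
            raise ValueError("random-forest imputation needs >= 2 columns")
        return self

    def sample(self, X, rng):
        rng = np.random.default_rng(rng)
        X = np.asarray(X, dtype=float)
        mask = np.isnan(X)
        out = X.copy()
        if not mask.any():
            return out
        out[mask] = np.broadcast_to(np.nanmean(X, axis=0), X.shape)[mask]
        todo = np.flatnonzero(mask.any(axis=0))
        self.deltas_ = []
        prev = np.inf
        previous = out.copy()
        for _ in range(self.max_iter):
            old = out.copy()
            for j in todo:
                obs, mis = ~mask[:, j], mask[:, j]
                others = np.delete(np.arange(X.shape[1]), j)
                rf = RandomForestRegressor(
                    n_estimators=self.n_estimators,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                    n_jobs=1,
                )
                rf.fit(out[np.ix_(obs, others)], X[obs, j])
                out[mis, j] = rf.predict(out[np.ix_(mis, others)])
            delta = float(((out - old)[mask] ** 2).sum() / ((out[mask] ** 2).sum() + 1e-12))
            self.deltas_.append(delta)
            if delta >= prev:
                return previous  # criterion stopped decreasing
            prev = delta
            previous = out.copy()
        return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

ENGINES = {
    "knn": KNNBootstrapImputer,
    "mle": EMGaussianImputer,
    "norm": ChainedNormImputer,
    "pca": IterativePCAImputer,
    "rf": RandomForestImputer,
}

#: Default scope per engine: the normal-model engine is global, all others
#: are applied experimental-condition-wise.
DEFAULT_SCOPE = {
    "knn": "condition",
    "mle": "condition",
    "norm": "global",
    "pca": "condition",
    "rf": "condition",
}


class MultipleImputer(BaseEstimator):
    """Multiple imputation: D stochastic completions of a quantification table.

    Parameters
    ----------
    method : {"knn", "mle", "norm", "pca", "rf"}
        Imputation engine.
    n_draws : int or None
        Number of completed datasets; ``None`` applies the draw rule
        (ceiling of the missing percentage, floored at 2).
    scope : {"condition", "global"} or None
        ``None`` uses the engine default ("global" for norm, condition-wise
        otherwise).
    random_state : int or None
        Master seed; draw d uses a child stream spawned from it.
    engine_params : dict or None
        Extra keyword arguments for the engine.

    Attributes
    ----------
    ensemble_ : ImputationEnsemble
        The D completed matrices, after :meth:`fit`.
    """

    def __init__(
        self,
        method: str = "mle",
        n_draws: int | None = None,
        scope: str | None = None,
        random_state: int | None = None,
        engine_params: dict | None = None,
    ):
        self.method = method
        self.n_draws = n_draws
        self.scope = scope
        self.random_state = random_state
        self.engine_params = engine_params

    def fit(self, table: QuantTable, y=None):
        if self.method not in ENGINES:
            raise ValueError(f"unknown imputation method: {self.method!r}")
        scope = self.scope or DEFAULT_SCOPE[self.method]
        if scope not in ("condition", "global"):
            raise ValueError(f"unknown scope: {scope!r}")
        D = self.n_draws
        if D is None:
            D = choose_num_draws(table.missing_proportion)
        if D < 1:
            raise ValueError("n_draws must be >= 1")

        blocks = (
            [np.arange(table.n_samples)]
            if scope == "global"
            else [table.condition_columns(c) for c in table.conditions]
        )
        params = self.engine_params or {}
        engines = []
        for cols in blocks:
            if not np.isnan(table.values[:, cols]).any():
                engines.append(None)  # complete block: nothing to impute
                continue
            eng = ENGINES[self.method](**params)
            eng.fit(table.values[:, cols])
            engines.append(eng)

        master = np.random.SeedSequence(
            self.random_state if self.random_state is not None else 0
        )
        data = np.empty((D,) + table.values.shape)
        for d, ss in enumerate(master.spawn(D)):
            rngs = [np.random.default_rng(s) for s in ss.spawn(len(blocks))]
            for cols, eng, rng in zip(blocks, engines, rngs):
                if eng is None:
                    data[d][:, cols] = table.values[:, cols]
                else:
                    data[d][:, cols] = eng.sample(table.values[:, cols], rng)
        self.ensemble_ = ImputationEnsemble(
            data=data,
            source=table,
            method=self.method,
            scope=scope,
            seed=self.random_state,
        )
        return self

    def fit_transform(self, table: QuantTable, y=None) -> np.ndarray:
        return self.fit(table).ensemble_.data


def multi_impute(
    table: QuantTable,
    method: str = "mle",
    D: int | None = None,
    scope: str | None = None,
    seed: int | None = None,
    **engine_params,
) -> ImputationEnsemble:
    """Build a D-draw imputation ensemble (functional front-end)."""
    imp = MultipleImputer(
        method=method,
        n_draws=D,
        scope=scope,
        random_state=seed,
        engine_params=engine_params or None,
    )
    return imp.fit(table).ensemble_


# -- single-draw functional wrappers ----------------------------------------

def _single(engine, X, seed):
    rng = np.random.default_rng(seed)
    engine.fit(X)
    return engine.sample(X, rng)


def impute_knn(X, k: int = 10, seed=None, bootstrap: bool = False):
    """One kNN completion of a matrix (deterministic unless ``bootstrap``)."""
    return _single(KNNBootstrapImputer(n_neighbors=k, bootstrap=bootstrap), X, seed)


def impute_mle(X, conditions=None, seed=None):
    """One EM-Gaussian draw; per-condition blocks when labels are given."""
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    if conditions is None:
        return _single_with_rng(EMGaussianImputer(), X, rng)
    conditions = np.asarray(conditions)
    out = X.copy()
    for c in dict.fromkeys(conditions):
        cols = np.flatnonzero(conditions == c)
        out[:, cols] = _single_with_rng(EMGaussianImputer(), X[:, cols], rng)
    return out


def _single_with_rng(engine, X, rng):
    engine.fit(X)
    return engine.sample(X, rng)


def impute_norm(X, seed=None, n_cycles: int = 10):
    """One chained-equations (normal-model) draw, global scope."""
    return _single(ChainedNormImputer(n_cycles=n_cycles), X, seed)


def impute_pca(X, n_components: int = 2, seed=None, noise: bool = True):
    """One iterative-PCA completion (+ residual noise unless disabled)."""
    return _single(IterativePCAImputer(n_components=n_components, noise=noise), X, seed)


def impute_rf(X, n_trees: int = 100, seed=None):
    """One missForest-style completion."""
    return _single(RandomForestImputer(n_estimators=n_trees), X, seed)
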