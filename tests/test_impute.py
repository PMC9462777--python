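"""Imputation engines and the multiple-imputation orchestrator."""
import numpy as np
import pytest

from miprot.impute import (
    ChainedNormImputer,
    EMGaussianImputer,
    IterativePCAImputer,
    KNNBootstrapImputer,
    RandomForestImputer,
    choose_num_draws,
    impute_knn,
    multi_impute,
)
from miprot.simulate import MarDesign2Spec, ampute, simulate_mar_design2

from conftest import make_table

ENGINES = {
    "knn": KNNBootstrapImputer(n_neighbors=2),
    "mle": EMGaussianImputer(),
    "norm": ChainedNormImputer(),
    "pca": IterativePCAImputer(n_components=1),
    "rf": RandomForestImputer(n_estimators=10),
}


class TestDrawRule:
    @pytest.mark.parametrize(
        "prop,expected",
        [(0.005, 2), (0.10, 10), (0.062, 7), (0.0, 2), (0.01, 2), (0.249, 25)],
    )
    def test_number_of_draws(self, prop, expected):
        assert choose_num_draws(prop) == expected

    def test_invalid_proportion_rejected(self):
        with pytest.raises(ValueError):
            choose_num_draws(1.0)


@pytest.mark.parametrize("name", list(ENGINES))
def test_complete_input_returned_unchanged(name):
    rng = np.random.default_rng(0)
    X = rng.normal(size=(12, 5))
    eng = ENGINES[name]
    eng.fit(X)
    out = eng.sample(X, rng)
    np.testing.assert_array_equal(out, X)


@pytest.mark.parametrize("name", list(ENGINES))
def test_observed_cells_preserved_exactly(name):
    rng = np.random.default_rng(1)
    X = rng.normal(20, 2, size=(30, 6))
    Xm = X.copy()
    miss = rng.random(X.shape) < 0.15
    Xm[miss] = np.nan
    eng = ENGINES[name]
    eng.fit(Xm)
    out = eng.sample(Xm, rng)
    obs = ~np.isnan(Xm)
    np.testing.assert_array_equal(out[obs], Xm[obs])
    assert np.isfinite(out).all()


class TestKNN:
    def test_duplicate_row_fills_from_zero_distance_neighbour(self):
        X = np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [1.0, 2.0, 3.0, np.nan],
                [50.0, 60.0, 70.0, 80.0],
            ]
        )
        out = impute_knn(X, k=1)
        assert out[1, 3] == 4.0

    def test_matches_bruteforce_neighbour_means(self):
        # donors complete, one target row: nan-Euclidean ordering reduces to
        # plain Euclidean over the target's observed columns
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 4))
        Xm = X.copy()
        Xm[0, 2] = np.nan
        out = impute_knn(Xm, k=2)
        d = np.sqrt(((X[1:, [0, 1, 3]] - Xm[0, [0, 1, 3]]) ** 2).sum(axis=1))
        nearest = 1 + np.argsort(d)[:2]
        np.testing.assert_allclose(out[0, 2], X[nearest, 2].mean(), rtol=1e-10)

    def test_k_larger_than_donor_pool_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            KNNBootstrapImputer(n_neighbors=10).fit(np.ones((3, 3)))

    def test_heavily_missing_row_falls_back_to_row_mean(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 6))
        X[0, :4] = np.nan  # 4/6 missing > 50%
        eng = KNNBootstrapImputer(n_neighbors=2, bootstrap=False)
        out = eng.fit(X).sample(X, rng)
        np.testing.assert_allclose(out[0, :4], X[0, 4:].mean())


class TestEMGaussian:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(10)
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        X = rng.multivariate_normal([1.0, -1.0], cov, size=6000)
        Xm = X.copy()
        Xm[:1500, 1] = np.nan
        return EMGaussianImputer().fit(Xm), Xm

    def test_draw_mean_matches_conditional_gaussian(self, fitted):
        em, Xm = fitted
        rng = np.random.default_rng(11)
        draws = np.array([em.sample(Xm[:1], rng)[0, 1] for _ in range(1000)])
        theory = -1.0 + 0.8 * (Xm[0, 0] - 1.0)
        # 3 x (MC s.e. of the mean + parameter-estimation slack)
        assert abs(draws.mean() - theory) < 3 * (0.6 / np.sqrt(1000) + 0.03)

    def test_draw_variance_matches_conditional_gaussian(self, fitted):
        em, Xm = fitted
        rng = np.random.default_rng(12)
        draws = np.array([em.sample(Xm[:1], rng)[0, 1] for _ in range(1000)])
        assert abs(draws.var() - 0.36) < 0.08

    def test_transform_is_deterministic_conditional_mean(self, fitted):
        em, Xm = fitted
        a = em.transform(Xm[:5])
        b = em.transform(Xm[:5])
        np.testing.assert_array_equal(a, b)


class TestChainedNorm:
    def test_recovers_linear_relation_between_columns(self):
        rng = np.random.default_rng(20)
        x = rng.normal(size=400)
        y = 2.0 * x + 1.0 + rng.normal(0, 0.1, size=400)
        X = np.column_stack([x, y])
        Xm = X.copy()
        Xm[:40, 1] = np.nan
        out = ChainedNormImputer().fit(Xm).sample(Xm, rng)
        resid = out[:40, 1] - (2.0 * x[:40] + 1.0)
        assert abs(resid.mean()) < 0.1
        assert np.abs(resid).max() < 1.0

    def test_different_seeds_give_different_imputations(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(50, 4))
        X[:10, 0] = np.nan
        eng = ChainedNormImputer().fit(X)
        a = eng.sample(X, np.random.default_rng(1))
        b = eng.sample(X, np.random.default_rng(2))
        assert not np.array_equal(a[:10, 0], b[:10, 0])


class TestIterativePCA:
    def test_rank_one_matrix_recovered_exactly(self):
        u = np.arange(1.0, 11.0)
        v = np.array([1.0, 0.5, 2.0, 1.5])
        X = np.outer(u, v)
        Xm = X.copy()
        for i, j in [(0, 1), (3, 2), (5, 0), (7, 3), (9, 2)]:
            Xm[i, j] = np.nan
        eng = IterativePCAImputer(n_components=1, noise=False, tol=1e-10)
        out = eng.fit(Xm).sample(Xm, np.random.default_rng(0))
        np.testing.assert_allclose(out, X, atol=1e-6)

    def test_between_draw_spread_matches_residual_rmse(self):
        rng = np.random.default_rng(30)
        X = np.outer(rng.normal(size=60), rng.normal(size=5)) + rng.normal(
            0, 0.3, size=(60, 5)
        )
        Xm = X.copy()
        Xm[0, 0] = np.nan
        eng = IterativePCAImputer(n_components=1).fit(Xm)
        draws = np.array(
            [eng.sample(Xm, np.random.default_rng(s))[0, 0] for s in range(300)]
        )
        assert abs(draws.std() - eng.residual_rmse_) < 0.3 * eng.residual_rmse_ + 0.05


class TestRandomForest:
    def test_constant_column_imputed_exactly(self):
        rng = np.random.default_rng(40)
        X = rng.normal(size=(30, 4))
        X[:, 2] = 7.0
        X[:5, 2] = np.nan
        out = RandomForestImputer(n_estimators=10).fit(X).sample(X, rng)
        np.testing.assert_array_equal(out[:5, 2], 7.0)

    def test_change_sequence_non_increasing_until_stop(self):
        rng = np.random.default_rng(41)
        X = np.outer(rng.normal(size=40), np.ones(5)) + rng.normal(0, 0.2, (40, 5))
        Xm = X.copy()
        Xm[rng.random(X.shape) < 0.2] = np.nan
        eng = RandomForestImputer(n_estimators=10)
        eng.fit(Xm).sample(Xm, rng)
        deltas = eng.deltas_
        # every recorded step except possibly the last decreases
        assert all(b < a for a, b in zip(deltas[:-2], deltas[1:-1]))


class TestMultiImpute:
    @pytest.fixture(scope="class")
    def amputed(self):
        table, _ = simulate_mar_design2(MarDesign2Spec(n_analytes=100, n_de=20, seed=0))
        return ampute(table, 0.10, seed=0)

    def test_draw_count_follows_rule(self, amputed):
        ens = multi_impute(amputed, method="mle", seed=0)
        assert ens.n_draws == 10

    def test_complete_table_gives_identical_draws(self):
        table, _ = simulate_mar_design2(MarDesign2Spec(n_analytes=50, n_de=10, seed=1))
        ens = multi_impute(table, method="mle", D=3, seed=1)
        np.testing.assert_array_equal(ens.data[0], ens.data[1])
        np.testing.assert_array_equal(ens.data[0], table.values)

    def test_deterministic_given_seed(self, amputed):
        a = multi_impute(amputed, method="mle", D=3, seed=5)
        b = multi_impute(amputed, method="mle", D=3, seed=5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_condition_scope_ignores_other_condition(self, amputed):
        # permuting condition-B values must not change condition-A imputations
        ens_a = multi_impute(amputed, method="mle", D=2, seed=7)
        shuffled = amputed.values.copy()
        rng = np.random.default_rng(0)
        cols_b = amputed.condition_columns("B")
        shuffled[:, cols_b] = shuffled[rng.permutation(100)][:, cols_b]
        table_b = make_table(shuffled, 10, 10)
        ens_b = multi_impute(table_b, method="mle", D=2, seed=7)
        cols_a = amputed.condition_columns("A")
        np.testing.assert_array_equal(
            ens_a.data[:, :, cols_a], ens_b.data[:, :, cols_a]
        )

    def test_unknown_method_rejected(self, amputed):
        with pytest.raises(ValueError, match="unknown imputation method"):
            multi_impute(amputed, method="median")

    def test_single_draw_warns(self, amputed):
        with pytest.warns(UserWarning, match="single-draw"):
            multi_impute(amputed, method="mle", D=1, seed=0)

    def test_default_scopes(self, amputed):
        assert multi_impute(amputed, method="mle", D=2, seed=0).scope == "condition"
        assert multi_impute(amputed, method="norm", D=2, seed=0).scope == "global"
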