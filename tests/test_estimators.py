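"""FC estimator tests, including the independent-solver oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.base import clone

from regconn.estimators import (
    GraphicalLassoFC,
    GraphicalRidgeFC,
    InsufficientDataError,
    PairwiseCorrelation,
    PartialCorrelation,
    PCRegressionFC,
    make_estimator,
    zscore,
)
from regconn.simulate import GroundTruthNetwork, simulate_session


def _session_matrix(rng, T, p, mix=None):
    X = rng.standard_normal((T, p))
    if mix is not None:
        X = X @ mix
    return X


class TestZScore:
    def test_exact_small_column(self):
        out = zscore(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 9.0]]))
        np.testing.assert_allclose(out[:, 0], [-1.224744871, 0.0, 1.224744871])
        assert out.mean(axis=0) == pytest.approx([0, 0], abs=1e-12)
        assert out.std(axis=0) == pytest.approx([1, 1], abs=1e-12)

    def test_idempotent(self, rng):
        X = zscore(_session_matrix(rng, 50, 4))
        np.testing.assert_allclose(zscore(X), X, atol=1e-12)

    def test_constant_column_names_the_node(self, rng):
        X = _session_matrix(rng, 30, 3)
        X[:, 2] = 5.0
        with pytest.raises(ValueError, match="node 2"):
            zscore(X)


class TestPairwise:
    def test_duplicate_and_negated_columns(self, rng):
        x = rng.standard_normal(40)
        X = np.column_stack([x, x + 0.0, -x, rng.standard_normal(40)])
        fc = PairwiseCorrelation().fit(X).connectivity_
        assert fc[0, 1] == pytest.approx(1.0)
        assert fc[0, 2] == pytest.approx(-1.0)
        assert np.all(np.diag(fc) == 0)
        assert np.abs(fc).max() <= 1.0 + 1e-12

    def test_toy_matrix_matches_bruteforce_formula(self):
        X = np.array([[1.0, 2.0, 0.5], [2.0, 1.0, 1.5], [4.0, 3.0, 1.0], [0.0, 2.0, 3.0]])
        fc = PairwiseCorrelation().fit(X).connectivity_
        for i in range(3):
            for j in range(i + 1, 3):
                a, b = X[:, i] - X[:, i].mean(), X[:, j] - X[:, j].mean()
                r = (a @ b) / np.sqrt((a @ a) * (b @ b))
                assert fc[i, j] == pytest.approx(r, abs=1e-12)


class TestPartial:
    def test_chain_conditional_independence(self, rng):
        # A -> B -> C: partial correlation of (A, C) given B vanishes
        T = 60_000
        a = rng.standard_normal(T)
        b = 0.8 * a + rng.standard_normal(T)
        c = 0.8 * b + rng.standard_normal(T)
        fc = PartialCorrelation().fit(np.column_stack([a, b, c])).connectivity_
        assert abs(fc[0, 2]) < 0.02
        assert fc[0, 1] > 0.3 and fc[1, 2] > 0.3

    def test_independent_nodes_near_zero(self, rng):
        fc = PartialCorrelation().fit(_session_matrix(rng, 20_000, 6)).connectivity_
        assert np.abs(fc[np.triu_indices(6, 1)]).max() < 0.03

    def test_equivalence_with_residualization_oracle(self, rng):
        X = zscore(_session_matrix(rng, 200, 5, mix=rng.standard_normal((5, 5)) * 0.4 + np.eye(5)))
        fc = PartialCorrelation().fit(X).connectivity_
        for i in range(5):
            for j in range(i + 1, 5):
                others = [k for k in range(5) if k not in (i, j)]
                Z = np.column_stack([np.ones(len(X)), X[:, others]])
                ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
                rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
                r = (ri @ rj) / np.sqrt((ri @ ri) * (rj @ rj))
                assert fc[i, j] == pytest.approx(r, abs=1e-8)

    def test_insufficient_data_raises(self, rng):
        with pytest.raises(InsufficientDataError, match="insufficient data"):
            PartialCorrelation().fit(_session_matrix(rng, 50, 60))


def _penalized_objective_oracle(S, lam, penalty):
    """Generic solver for the penalized likelihood via L-BFGS-B.

    L1 off-diagonal entries are split into positive and negative parts so
    the problem stays smooth; the ridge version optimizes the symmetric
    matrix directly. Entirely independent of the package solvers.
    """
    p = S.shape[0]
    iu = np.triu_indices(p, 1)
    n_off = len(iu[0])

    def build(theta):
        P = np.zeros((p, p))
        np.fill_diagonal(P, theta[:p])
        if penalty == "l1":
            off = theta[p : p + n_off] - theta[p + n_off :]
        else:
            off = theta[p:]
        P[iu] = off
        return P + np.triu(P, 1).T

    def cost(theta):
        P = build(theta)
        w = np.linalg.eigvalsh(P)
        if w.min() <= 1e-10:
            return 1e10
        base = -np.log(w).sum() + (S * P).sum()
        if penalty == "l1":
            return base + 2 * lam * (theta[p:].sum())
        return base + 2 * lam * (theta[p:] ** 2).sum()

    if penalty == "l1":
        x0 = np.concatenate([1.0 / np.diag(S), np.full(2 * n_off, 0.01)])
        bounds = [(1e-6, None)] * p + [(0, None)] * (2 * n_off)
    else:
        x0 = np.concatenate([1.0 / np.diag(S), np.zeros(n_off)])
        bounds = [(1e-6, None)] * p + [(None, None)] * n_off
    res = minimize(cost, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 20_000, "ftol": 1e-15, "gtol": 1e-10})
    return build(res.x)


@pytest.fixture(scope="module")
def five_node_session():
    rng = np.random.default_rng(5)
    mix = np.eye(5) + 0.35 * rng.standard_normal((5, 5))
    return zscore(rng.standard_normal((300, 5)) @ mix)


class TestGraphicalLasso:
    def test_zero_penalty_matches_partial(self, rng):
        X = _session_matrix(rng, 2000, 8, mix=np.eye(8) + 0.2 * rng.standard_normal((8, 8)))
        a = GraphicalLassoFC(lambda1=0.0).fit(X).connectivity_
        b = PartialCorrelation().fit(X).connectivity_
        np.testing.assert_allclose(a, b, atol=1e-4)

    def test_large_penalty_fully_sparse(self, five_node_session):
        fc = GraphicalLassoFC(lambda1=5.0).fit(five_node_session).connectivity_
        assert np.all(fc == 0)

    def test_matches_independent_convex_solver(self, five_node_session):
        for lam in (0.02, 0.1):
            ours = GraphicalLassoFC(lambda1=lam, tol=1e-8).fit(five_node_session)
            P_oracle = _penalized_objective_oracle(
                five_node_session.T @ five_node_session / len(five_node_session), lam, "l1"
            )
            d = np.sqrt(np.diag(P_oracle))
            fc_oracle = -P_oracle / np.outer(d, d)
            np.fill_diagonal(fc_oracle, 0)
            np.testing.assert_allclose(ours.connectivity_, fc_oracle, atol=1e-4)

    def test_matches_sklearn_graphical_lasso(self, rng):
        from sklearn.covariance import graphical_lasso as sk_glasso

        X = zscore(_session_matrix(rng, 300, 30, mix=np.eye(30) + 0.15 * rng.standard_normal((30, 30))))
        S = X.T @ X / len(X)
        ours = GraphicalLassoFC(lambda1=0.05, tol=1e-7).fit(X)
        _, P_sk = sk_glasso(S, 0.05, tol=1e-8, max_iter=500)
        d = np.sqrt(np.diag(P_sk))
        fc_sk = -P_sk / np.outer(d, d)
        np.fill_diagonal(fc_sk, 0)
        np.testing.assert_allclose(ours.connectivity_, (fc_sk + fc_sk.T) / 2, atol=2e-4)

    def test_sparsity_nonincreasing_in_lambda(self, default_session):
        counts = []
        for lam in np.linspace(0.01, 0.3, 10):
            fc = GraphicalLassoFC(lambda1=lam).fit(default_session.data).connectivity_
            counts.append(int(np.sum(fc[np.triu_indices(100, 1)] != 0)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_works_below_t_equals_p(self, rng):
        X = _session_matrix(rng, 40, 60)
        fc = GraphicalLassoFC(lambda1=0.2).fit(X).connectivity_
        assert np.isfinite(fc).all()


class TestGraphicalRidge:
    def test_zero_penalty_matches_partial(self, rng):
        X = _session_matrix(rng, 2000, 8, mix=np.eye(8) + 0.2 * rng.standard_normal((8, 8)))
        a = GraphicalRidgeFC(lambda2=0.0).fit(X).connectivity_
        b = PartialCorrelation().fit(X).connectivity_
        np.testing.assert_allclose(a, b, atol=1e-4)

    def test_shrinkage_monotone(self, five_node_session):
        mags = [
            np.abs(GraphicalRidgeFC(lambda2=lam).fit(five_node_session).connectivity_).sum()
            for lam in (0.1, 0.5, 1.5, 4.0, 10.0)
        ]
        assert all(a > b for a, b in zip(mags, mags[1:]))

    def test_matches_independent_numeric_optimizer(self, five_node_session):
        for lam in (0.3, 1.0):
            ours = GraphicalRidgeFC(lambda2=lam).fit(five_node_session)
            P_oracle = _penalized_objective_oracle(
                five_node_session.T @ five_node_session / len(five_node_session), lam, "l2"
            )
            d = np.sqrt(np.diag(P_oracle))
            fc_oracle = -P_oracle / np.outer(d, d)
            np.fill_diagonal(fc_oracle, 0)
            np.testing.assert_allclose(ours.connectivity_, fc_oracle, atol=1e-4)


class TestPCRegression:
    def test_full_rank_limit_equals_multiple_regression(self, rng):
        X = zscore(_session_matrix(rng, 500, 7, mix=np.eye(7) + 0.3 * rng.standard_normal((7, 7))))
        est = PCRegressionFC(n_components=6).fit(X)
        B = np.zeros((7, 7))
        for j in range(7):
            others = [k for k in range(7) if k != j]
            B[j, others] = np.linalg.lstsq(X[:, others], X[:, j], rcond=None)[0]
        np.testing.assert_allclose(est.connectivity_, (B + B.T) / 2, atol=1e-6)

    def test_output_exactly_symmetric(self, rng):
        fc = PCRegressionFC(n_components=3).fit(_session_matrix(rng, 60, 6)).connectivity_
        np.testing.assert_array_equal(fc, fc.T)

    def test_matches_stepwise_pca_regression_oracle(self, rng):
        from sklearn.decomposition import PCA
        from sklearn.linear_model import LinearRegression

        X = zscore(_session_matrix(rng, 120, 6, mix=np.eye(6) + 0.3 * rng.standard_normal((6, 6))))
        k = 3
        est = PCRegressionFC(n_components=k).fit(X)
        B = np.zeros((6, 6))
        for j in range(6):
            others = [m for m in range(6) if m != j]
            pca = PCA(n_components=k).fit(X[:, others])
            scores = pca.transform(X[:, others])
            reg = LinearRegression(fit_intercept=True).fit(scores, X[:, j])
            B[j, others] = pca.components_.T @ reg.coef_
        np.testing.assert_allclose(est.connectivity_, (B + B.T) / 2, atol=1e-8)

    def test_component_count_bounds(self, rng):
        X = _session_matrix(rng, 30, 5)
        with pytest.raises(ValueError):
            PCRegressionFC(n_components=5).fit(X)
        with pytest.raises(ValueError):
            PCRegressionFC(n_components=0).fit(X)


class TestSharedInvariants:
    @pytest.mark.parametrize(
        "method,hyper", [("pairwise", None), ("partial", None), ("glasso", 0.08),
                         ("gridge", 1.0), ("pcreg", 5)]
    )
    def test_symmetric_zero_diagonal(self, rng, method, hyper):
        X = _session_matrix(rng, 120, 10, mix=np.eye(10) + 0.2 * rng.standard_normal((10, 10)))
        fc = make_estimator(method, hyperparameter=hyper).fit(X).connectivity_
        np.testing.assert_array_equal(fc, fc.T)
        assert np.all(np.diag(fc) == 0)
        if method in ("pairwise", "partial"):
            assert np.abs(fc).max() <= 1.0 + 1e-12

    @pytest.mark.parametrize("method,hyper", [("pairwise", None), ("partial", None), ("glasso", 0.08)])
    def test_node_permutation_equivariance(self, rng, method, hyper):
        X = _session_matrix(rng, 150, 8, mix=np.eye(8) + 0.25 * rng.standard_normal((8, 8)))
        perm = np.random.default_rng(1).permutation(8)
        fc = make_estimator(method, hyperparameter=hyper).fit(X).connectivity_
        fc_perm = make_estimator(method, hyperparameter=hyper).fit(X[:, perm]).connectivity_
        tol = 0 if method != "glasso" else 1e-5
        np.testing.assert_allclose(fc_perm, fc[np.ix_(perm, perm)], atol=tol)

    def test_partial_correlation_consistency_on_long_noiseless_session(self, small_net):
        """Estimates converge to the population partial correlation.

        The population precision of X = (I-W)^{-1}E is (I-W)^T (I-W); note
        its support strictly contains the structural skeleton (pairs with a
        common child pick up moralization fill-in), so consistency is
        checked against the theoretical matrix, not the raw skeleton.
        """
        p = small_net.n_nodes
        sess = simulate_session(small_net, 1000 * p, 0.0, rng_seed=3)
        fc = PartialCorrelation().fit(sess.data).connectivity_
        Theta = (np.eye(p) - small_net.weights).T @ (np.eye(p) - small_net.weights)
        d = np.sqrt(np.diag(Theta))
        pc_th = -Theta / np.outer(d, d)
        np.fill_diagonal(pc_th, 0.0)
        iu = np.triu_indices(p, 1)
        assert np.corrcoef(fc[iu], pc_th[iu])[0, 1] > 0.99
        assert np.abs(fc - pc_th)[iu].max() < 0.03
        est_support = np.abs(fc[iu]) > 0.02
        th_support = np.abs(pc_th[iu]) > 0.02
        jacc = (est_support & th_support).sum() / (est_support | th_support).sum()
        assert jacc > 0.8

    def test_sklearn_clone_and_params_roundtrip(self):
        est = GraphicalLassoFC(lambda1=0.07, tol=1e-6)
        est2 = clone(est)
        assert est2.get_params()["lambda1"] == 0.07
        est2.set_params(lambda1=0.2)
        assert est2.lambda1 == 0.2
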