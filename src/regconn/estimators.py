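"""Functional-connectivity estimators with a scikit-learn interface.

Every estimator consumes a timepoints x nodes activity matrix (z-scored
internally unless told otherwise), fits a symmetric node x node
connectivity matrix with a zero diagonal, and exposes it as
``connectivity_``. ``score(X)`` implements the shared held-out criterion:
each node's activity is predicted as the connectivity-weighted sum of the
other nodes' concurrent activity and scored by the coefficient of
determination, averaged over nodes — identical code for every method.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from ._solvers import glasso, gridge, precision_to_partial
from .simulate import TimeSeriesSession


class InsufficientDataError(ValueError):
    """Raised when an estimator needs more timepoints than were provided."""


def _as_array(X) -> np.ndarray:
    if isinstance(X, TimeSeriesSession):
        X = X.data
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D timepoints x nodes matrix")
    return X


def zscore(X):
    """Z-score each column (population SD). Accepts arrays or sessions.

    Raises a ValueError naming the first offending node if any column is
    constant. Returns the same container type it was given.
    """
    arr = _as_array(X)
    sd = arr.std(axis=0)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(f"node {bad[0]} has a constant time series; cannot z-score")
    out = (arr - arr.mean(axis=0)) / sd
    if isinstance(X, TimeSeriesSession):
        return TimeSeriesSession(out, X.noise_level, X.seed, X.tr)
    return out


class BaseFC(BaseEstimator):
    """Shared fit/score machinery for the five FC estimators."""

    #: short method label used in I/O sidecars and benchmark tables
    method = "base"

    def __init__(self, assume_scaled=False):
        self.assume_scaled = assume_scaled

    def _hyperparameter(self):
        return None

    def _correlation(self, X: np.ndarray) -> np.ndarray:
        """Sample correlation (T-denominator); data z-scored unless assume_scaled."""
        if not self.assume_scaled:
            X = zscore(X)
        S = X.T @ X / X.shape[0]
        return S, X.shape[0]

    def fit(self, X, y=None):
        X = _as_array(X)
        S, n = self._correlation(X)
        self.n_features_in_ = S.shape[0]
        self.n_samples_ = n
        self._fit_correlation(S, n)
        return self

    def _fit_correlation(self, S: np.ndarray, n_samples: int):  # pragma: no cover
        raise NotImplementedError

    def predict_timeseries(self, X) -> np.ndarray:
        """Predict each node from the concurrent activity of all other nodes."""
        X = _as_array(X)
        return X @ self.connectivity_.T

    def score(self, X, y=None) -> float:
        """Mean per-node R^2 (1 - SS_res/SS_tot, no refit intercept)."""
        X = _as_array(X)
        pred = self.predict_timeseries(X)
        ss_res = ((X - pred) ** 2).sum(axis=0)
        ss_tot = (X**2).sum(axis=0)
        return float(np.mean(1.0 - ss_res / ss_tot))


class PairwiseCorrelation(BaseFC):
    """Pearson correlation between each pair of nodes' time series."""

    method = "pairwise"

    def _fit_correlation(self, S, n_samples):
        d = np.sqrt(np.diag(S))
        C = S / np.outer(d, d)
        np.fill_diagonal(C, 0.0)
        self.connectivity_ = (C + C.T) / 2.0


class PartialCorrelation(BaseFC):
    """Unregularized partial correlation from the inverted correlation matrix."""

    method = "partial"

    def _fit_correlation(self, S, n_samples):
        p = S.shape[0]
        if n_samples <= p:
            raise InsufficientDataError(
                f"insufficient data: partial correlation needs more timepoints "
                f"than nodes (T={n_samples}, p={p})"
            )
        try:
            P = np.linalg.inv(S)
        except np.linalg.LinAlgError as err:
            raise InsufficientDataError(
                "insufficient data: sample correlation matrix is singular"
            ) from err
        self.precision_ = P
        self.connectivity_ = precision_to_partial(P)


class GraphicalLassoFC(BaseFC):
    """Partial correlation with an off-diagonal L1 penalty on the precision."""

    method = "glasso"

    def __init__(self, lambda1=0.1, tol=1e-5, max_iter=10_000, assume_scaled=False):
        super().__init__(assume_scaled=assume_scaled)
        self.lambda1 = lambda1
        self.tol = tol
        self.max_iter = max_iter

    def _hyperparameter(self):
        return self.lambda1

    def _fit_correlation(self, S, n_samples, precision_init=None):
        if self.lambda1 == 0:
            p = S.shape[0]
            if n_samples <= p:
                raise InsufficientDataError(
                    "insufficient data: lambda1=0 reduces to partial correlation, "
                    f"which needs T > p (T={n_samples}, p={p})"
                )
            P = np.linalg.inv(S)
            info = {"n_iter": 0, "max_change": 0.0, "converged": True}
        else:
            P, info = glasso(
                S,
                self.lambda1,
                precision_init=precision_init,
                tol=self.tol,
                max_iter=self.max_iter,
            )
        self.precision_ = P
        self.n_iter_ = info["n_iter"]
        self.solver_info_ = info
        self.connectivity_ = precision_to_partial(P)


class GraphicalRidgeFC(BaseFC):
    """Partial correlation with an off-diagonal squared-L2 precision penalty."""

    method = "gridge"

    def __init__(self, lambda2=1.0, tol=1e-8, max_iter=200, assume_scaled=False):
        super().__init__(assume_scaled=assume_scaled)
        self.lambda2 = lambda2
        self.tol = tol
        self.max_iter = max_iter

    def _hyperparameter(self):
        return self.lambda2

    def _fit_correlation(self, S, n_samples):
        if self.lambda2 == 0:
            p = S.shape[0]
            if n_samples <= p:
                raise InsufficientDataError(
                    "insufficient data: lambda2=0 reduces to partial correlation, "
                    f"which needs T > p (T={n_samples}, p={p})"
                )
        P, info = gridge(S, self.lambda2, tol=self.tol, max_iter=self.max_iter)
        self.precision_ = P
        self.n_iter_ = info["n_iter"]
        self.solver_info_ = info
        self.connectivity_ = precision_to_partial(P)


def _pca_basis(Z: np.ndarray):
    """SVD-based PCA of already-centered columns.

    Returns (scores, loadings) with components ordered by explained variance
    and signs fixed so each component's largest-magnitude loading is positive.
    """
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    V = Vt.T
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])])
    flip[flip == 0] = 1.0
    V = V * flip
    scores = Z @ V
    return scores, V


class PCRegressionFC(BaseFC):
    """Per-node principal-components regression, back-projected and symmetrized.

    For each target node, PCA is run on the other nodes' time series; the
    target is regressed (no intercept; columns are z-scored) on the
    ``n_components`` top-variance scores, and the coefficients are projected
    back onto the predictor nodes to fill the target's row. The matrix is
    then averaged with its transpose.
    """

    method = "pcreg"

    def __init__(self, n_components=10, assume_scaled=False):
        super().__init__(assume_scaled=assume_scaled)
        self.n_components = n_components

    def _hyperparameter(self):
        return self.n_components

    def fit(self, X, y=None):
        X = _as_array(X)
        if not self.assume_scaled:
            X = zscore(X)
        T, p = X.shape
        k = self.n_components
        if not (1 <= k <= p - 1):
            raise ValueError(f"n_components must be in [1, p-1]; got {k} with p={p}")
        if k > T:
            raise ValueError(f"n_components must not exceed timepoints (T={T})")
        M = np.zeros((p, p))
        others = np.arange(p)
        for j in range(p):
            idx = np.delete(others, j)
            scores, V = _pca_basis(X[:, idx])
            sc = scores[:, :k]
            beta = np.linalg.lstsq(sc, X[:, j], rcond=None)[0]
            M[j, idx] = V[:, :k] @ beta
        M = (M + M.T) / 2.0
        np.fill_diagonal(M, 0.0)
        self.n_features_in_ = p
        self.n_samples_ = T
        self.connectivity_ = M
        return self

    def _fit_correlation(self, S, n_samples):
        raise NotImplementedError("PC regression operates on time series, not moments")


#: registry used by the selection harness, benchmarks and the CLI
ESTIMATORS = {
    "pairwise": PairwiseCorrelation,
    "partial": PartialCorrelation,
    "glasso": GraphicalLassoFC,
    "gridge": GraphicalRidgeFC,
    "pcreg": PCRegressionFC,
}

#: name of the hyperparameter constructor argument per regularized method
HYPERPARAM_ARG = {"glasso": "lambda1", "gridge": "lambda2", "pcreg": "n_components"}


def make_estimator(method: str, hyperparameter=None, **kwargs):
    """Instantiate an estimator by its method label."""
    if method not in ESTIMATORS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(ESTIMATORS)}")
    if hyperparameter is not None:
        if method not in HYPERPARAM_ARG:
            raise ValueError(f"method {method!r} takes no hyperparameter")
        kwargs[HYPERPARAM_ARG[method]] = hyperparameter
    return ESTIMATORS[method](**kwargs)


def pairwise_correlation(session):
    """Functional wrapper: pairwise-correlation FC matrix for one session."""
    return PairwiseCorrelation().fit(session).connectivity_


def partial_correlation(session):
    """Functional wrapper: unregularized partial-correlation FC matrix."""
    return PartialCorrelation().fit(session).connectivity_


def graphical_lasso_fc(session, lambda1):
    """Functional wrapper: graphical-lasso FC matrix at a given lambda1."""
    return GraphicalLassoFC(lambda1=lambda1).fit(session).connectivity_


def graphical_ridge_fc(session, lambda2):
    """Functional wrapper: graphical-ridge FC matrix at a given lambda2."""
    return GraphicalRidgeFC(lambda2=lambda2).fit(session).connectivity_


def pc_regression_fc(session, n_components):
    """Functional wrapper: PC-regression FC matrix with a given PC count."""
    return PCRegressionFC(n_components=n_components).fit(session).connectivity_
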