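"""Cross-validated hyperparameter selection for the regularized estimators.

The criterion is method-agnostic: within a session, 10 contiguous folds of
timepoints are held out in turn, the FC matrix is fit on the remaining
folds, each node's held-out activity is predicted as the connectivity-
weighted sum of the other nodes' concurrent held-out activity, and the fit
is summarized as the coefficient of determination averaged over nodes and
folds. The selected hyperparameter maximizes this mean R^2; if the maximum
falls on the boundary of the tested range, the range is expanded and the
search repeated.

Search strategy: the held-out R^2 profile is smooth and unimodal in the
regularization strength, so a single-fold pilot pass first descends a
coarse subsample of the grid to locate the peak, and every fold then
evaluates the fine grid (steps of 0.005 for lambda1, 0.1 for lambda2,
5 PCs) in a window around it, walking outward whenever the full-fold
argmax touches the window edge. Iterative solvers are warm-started from
the nearest previously solved value. ``search="full"`` instead evaluates
the entire grid with every fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._solvers import glasso, gridge, precision_to_partial
from .estimators import (
    HYPERPARAM_ARG,
    InsufficientDataError,
    _as_array,
    make_estimator,
    zscore,
)

GRID_STEPS = {"glasso": 0.005, "gridge": 0.1, "pcreg": 5}
COARSE_FACTOR = 5  # pilot pass visits every 5th fine-grid value
MIN_PCS = 10


@dataclass
class SelectionResult:
    """Outcome of a cross-validated hyperparameter search."""

    method: str
    best_value: float
    grid: np.ndarray
    mean_r2_per_value: np.ndarray
    fold_count: int
    expansions: int
    boundary: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def best_r2(self) -> float:
        return float(np.max(self.mean_r2_per_value))


def make_folds(n_timepoints: int, n_folds: int = 10):
    """Deterministic contiguous fold index blocks."""
    if n_timepoints < 2 * n_folds:
        raise ValueError(
            f"session too short for {n_folds}-fold CV with >= 2 timepoints per fold"
        )
    return np.array_split(np.arange(n_timepoints), n_folds)


class _CVHarness:
    """Per-session fold bookkeeping shared by every method.

    Caches per-(fold, value) held-out R^2 and warm-start states, so search
    strategies can revisit values for free.
    """

    def __init__(self, X, n_folds=10, cv_tol=3e-4):
        X = _as_array(X)
        self.X = zscore(X)
        self.T, self.p = self.X.shape
        self.folds = make_folds(self.T, n_folds)
        self.n_folds = n_folds
        self.cv_tol = cv_tol
        G_full = self.X.T @ self.X
        self.held = []
        self.S_train = []
        self.T_train = []
        self.ss_tot = []
        for f in self.folds:
            Xf = self.X[f]
            Ttr = self.T - len(f)
            self.held.append(Xf)
            self.S_train.append((G_full - Xf.T @ Xf) / Ttr)
            self.T_train.append(Ttr)
            self.ss_tot.append((Xf**2).sum(axis=0))
        self._r2_cache: dict[tuple[int, str, float], float] = {}
        self._warm: list[dict] = [dict() for _ in range(n_folds)]
        self._pcreg_r2: list[dict] | None = None

    def r2_of_fc(self, fold: int, fc: np.ndarray) -> float:
        Xf = self.held[fold]
        pred = Xf @ fc.T
        ss_res = ((Xf - pred) ** 2).sum(axis=0)
        return float(np.mean(1.0 - ss_res / self.ss_tot[fold]))

    def _fold_r2(self, fold: int, method: str, value: float) -> float:
        key = (fold, method, round(float(value), 6))
        if key in self._r2_cache:
            return self._r2_cache[key]
        if method in ("pairwise", "partial"):
            est = make_estimator(method, assume_scaled=True)
            est._fit_correlation(self.S_train[fold], self.T_train[fold])
            fc = est.connectivity_
        elif method == "glasso":
            cache = self._warm[fold]
            P0 = cache[min(cache, key=lambda l: abs(l - value))] if cache else None
            P, _ = glasso(self.S_train[fold], value, precision_init=P0, tol=self.cv_tol)
            cache[round(float(value), 6)] = P
            fc = precision_to_partial(P)
        elif method == "gridge":
            cache = self._warm[fold]
            d0 = cache[min(cache, key=lambda l: abs(l - value))] if cache else None
            P, _ = gridge(self.S_train[fold], value, tol=1e-7, diag_init=d0)
            cache[round(float(value), 6)] = np.diag(P).copy()
            fc = precision_to_partial(P)
        elif method == "pcreg":
            self._ensure_pcreg(int(value))
            r2 = self._pcreg_r2[fold][int(value)]
            self._r2_cache[key] = r2
            return r2
        else:
            raise ValueError(f"unknown method {method!r}")
        r2 = self.r2_of_fc(fold, fc)
        self._r2_cache[key] = r2
        return r2

    def _ensure_pcreg(self, *ks: int):
        """Evaluate PC regression for the given PC counts on every fold.

        The per-(fold, target) SVD is computed once; because component
        scores are orthogonal, every PC count shares the prefix of one
        least-squares solution, so extra counts are nearly free.
        """
        if self._pcreg_r2 is None:
            self._pcreg_r2 = [dict() for _ in range(self.n_folds)]
        ks = sorted(set(int(k) for k in ks) - set(self._pcreg_r2[0]))
        if not ks:
            return
        others = np.arange(self.p)
        for fold in range(self.n_folds):
            # PCA of the predictors reduces to the eigendecomposition of the
            # training Gram submatrix, and the component betas to eigenvector
            # projections of its deleted column — no time-series pass needed
            G = self.S_train[fold] * self.T_train[fold]
            rows = {k: np.zeros((self.p, self.p)) for k in ks}
            for j in range(self.p):
                idx_cols = np.delete(others, j)
                Gj = G[np.ix_(idx_cols, idx_cols)]
                evals, V = np.linalg.eigh(Gj)
                evals, V = evals[::-1], V[:, ::-1]  # descending variance
                g = G[idx_cols, j]
                betas = (V.T @ g) / np.clip(evals, 1e-300, None)
                for k in ks:
                    rows[k][j, idx_cols] = V[:, :k] @ betas[:k]
            for k in ks:
                M = (rows[k] + rows[k].T) / 2.0
                np.fill_diagonal(M, 0.0)
                self._pcreg_r2[fold][k] = self.r2_of_fc(fold, M)

    def mean_r2(self, method: str, value: float, folds=None) -> float:
        folds = range(self.n_folds) if folds is None else folds
        return float(np.mean([self._fold_r2(f, method, value) for f in folds]))


def cv_r2(session, method: str, value=None, n_folds: int = 10, cv_tol: float = 3e-4):
    """Mean held-out R^2 for one method at one hyperparameter value."""
    harness = _CVHarness(session, n_folds, cv_tol)
    try:
        return harness.mean_r2(method, 0.0 if value is None else value)
    except InsufficientDataError as err:
        raise InsufficientDataError(f"{err} (during {n_folds}-fold CV)") from err


def default_grid(method: str, p: int | None = None) -> np.ndarray:
    """Initial hyperparameter grids bracketing the expected optima."""
    if method == "glasso":
        return np.round(np.arange(0.005, 0.1501, 0.005), 4)
    if method == "gridge":
        return np.round(np.arange(0.1, 3.001, 0.1), 4)
    if method == "pcreg":
        if p is None:
            raise ValueError("pcreg grid needs the node count p")
        grid = np.arange(MIN_PCS, p - 1, 5)
        if grid.size == 0 or grid[-1] != p - 1:
            grid = np.append(grid, p - 1)
        return grid
    raise ValueError(f"method {method!r} has no hyperparameter grid")


def select_hyperparameter(
    session,
    method: str,
    initial_grid=None,
    n_folds: int = 10,
    max_expansions: int = 10,
    search: str = "pilot",
    cv_tol: float = 3e-4,
) -> SelectionResult:
    """Select a regularization hyperparameter by held-out time-series R^2.

    With ``search="pilot"`` (default) a single-fold pass locates the R^2
    peak on a coarse subsample of the grid and all folds then evaluate a
    fine-step window around it, walking outward while the argmax sits on
    the window edge; ``search="full"`` evaluates every grid value with
    every fold. Maxima on the boundary of the initial range trigger range
    expansion (one grid-width appended per expansion, up to
    ``max_expansions``); PC regression is never allowed below 10 PCs nor
    above p - 1.
    """
    if method not in HYPERPARAM_ARG:
        raise ValueError(f"method {method!r} has no hyperparameter to select")
    harness = _CVHarness(session, n_folds, cv_tol)
    step = GRID_STEPS[method]
    grid = (
        np.asarray(initial_grid, dtype=float)
        if initial_grid is not None
        else default_grid(method, harness.p)
    )
    grid = np.unique(np.round(grid, 6))
    if method == "pcreg":
        hard_lo = MIN_PCS
        hard_hi = min(harness.p - 1, min(harness.T_train))
        grid = grid[(grid >= hard_lo) & (grid <= hard_hi)]
    else:
        hard_lo, hard_hi = step, np.inf
        grid = grid[grid >= hard_lo - 1e-12]
    if grid.size == 0:
        raise ValueError("empty hyperparameter grid after applying bounds")
    init_lo, init_hi = float(grid[0]), float(grid[-1])
    span = max(init_hi - init_lo, step)

    def snap(v):
        # keep values on the fine lattice anchored at the grid's low end
        return round(init_lo + round((v - init_lo) / step) * step, 6)

    expansions = 0
    hi_limit = init_hi  # grows by one span per expansion
    evaluated: dict[float, float] = {}  # full-fold mean R^2 per value

    def full_eval(v) -> float:
        v = snap(v)
        if v not in evaluated:
            evaluated[v] = harness.mean_r2(method, v)
        return evaluated[v]

    if method == "pcreg" or search == "full" or grid.size <= 4:
        if method == "pcreg":
            harness._ensure_pcreg(*grid)  # one SVD pass shared by all PC counts
        for v in grid:
            full_eval(v)
        # boundary expansion on the full profile
        while expansions < max_expansions:
            vals = np.asarray(sorted(evaluated))
            r2s = np.array([evaluated[v] for v in vals])
            best = float(vals[np.argmax(r2s)]) if method != "pcreg" else float(
                vals[np.where(r2s == r2s.max())[0][-1]]
            )
            hi = vals[-1]
            lo = vals[0]
            if np.isclose(best, hi) and hi + step <= hard_hi:
                expansions += 1
                new = [
                    snap(v)
                    for v in np.arange(hi + step * COARSE_FACTOR, hi + span + step, step * COARSE_FACTOR)
                    if v <= hard_hi
                ]
                new += [
                    snap(v)
                    for v in np.arange(hi + step, min(hi + COARSE_FACTOR * step, hard_hi) + step / 2, step)
                ]
            elif np.isclose(best, lo) and lo - step >= hard_lo:
                expansions += 1
                new = [snap(v) for v in np.arange(max(hard_lo, lo - span), lo, step)]
            else:
                break
            if method == "pcreg":
                harness._ensure_pcreg(*new)
            for v in new:
                full_eval(v)
    else:
        # --- pilot pass: fold 0 only, descending the coarse subsample ---
        coarse = list(grid[::-COARSE_FACTOR])
        if grid[0] not in coarse:
            coarse.append(float(grid[0]))
        pilot: dict[float, float] = {}

        def pilot_eval(v):
            v = snap(v)
            if v not in pilot:
                pilot[v] = harness.mean_r2(method, v, folds=[0])
            return pilot[v]

        pilot_exp = 0
        i = 0
        while i < len(coarse):
            v = float(coarse[i])
            pilot_eval(v)
            best_v = max(pilot, key=pilot.get)
            # stop descending once two coarse steps past the running peak
            below = [u for u in pilot if u < best_v]
            if len(below) >= 2:
                break
            # expand upward if the top of the range looks like the peak
            if (
                i == len(coarse) - 1
                and np.isclose(best_v, max(pilot))
                and pilot_exp < max_expansions
                and max(pilot) + step <= hard_hi
            ):
                top = max(pilot)
                new = [
                    snap(u)
                    for u in np.arange(top + step * COARSE_FACTOR, top + span + step, step * COARSE_FACTOR)
                    if u <= hard_hi
                ]
                if new:
                    coarse = sorted(set(coarse) | set(new), reverse=True)
                    i = 0
                    pilot_exp += 1
                    hi_limit = max(hi_limit, max(new))
                    expansions = pilot_exp
                    continue
            i += 1
        anchor = max(pilot, key=pilot.get)

        # --- full-fold window around the pilot anchor, walking outward ---
        window = [
            snap(v)
            for v in np.arange(anchor - COARSE_FACTOR * step, anchor + COARSE_FACTOR * step + step / 2, step)
            if hard_lo - 1e-12 <= v <= min(hi_limit, hard_hi)
        ]
        for v in window:
            full_eval(v)
        while True:
            vals = np.asarray(sorted(evaluated))
            r2s = np.array([evaluated[v] for v in vals])
            best = float(vals[np.argmax(r2s)])
            lo, hi = float(vals[0]), float(vals[-1])
            if np.isclose(best, lo) and lo - step >= hard_lo:
                full_eval(lo - step)
            elif np.isclose(best, hi) and hi + step <= hard_hi:
                if hi + step > hi_limit:
                    if expansions >= max_expansions:
                        break
                    expansions += 1
                    hi_limit += span
                full_eval(hi + step)
            else:
                break

    values = np.asarray(sorted(evaluated))
    r2s = np.array([evaluated[v] for v in values])
    top = np.where(r2s == r2s.max())[0]
    # ties: least regularization — smallest lambda, largest PC count
    best = float(values[top[-1]]) if method == "pcreg" else float(values[top[0]])
    boundary = bool(
        (np.isclose(best, values[0]) and values[0] - step >= hard_lo)
        or (np.isclose(best, values[-1]) and values[-1] + step <= hard_hi)
    )
    if method == "pcreg":
        best = int(round(best))
    return SelectionResult(
        method=method,
        best_value=best,
        grid=values,
        mean_r2_per_value=r2s,
        fold_count=n_folds,
        expansions=expansions,
        boundary=boundary,
        meta={"search": search, "cv_tol": cv_tol},
    )


def fit_with_selection(session, method: str, n_folds: int = 10, **kwargs):
    """Select the hyperparameter for a session, then fit the final estimator.

    Returns (estimator, SelectionResult or None). Unregularized methods skip
    selection.
    """
    if method not in HYPERPARAM_ARG:
        est = make_estimator(method).fit(session)
        return est, None
    sel = select_hyperparameter(session, method, n_folds=n_folds, **kwargs)
    est = make_estimator(method, hyperparameter=sel.best_value).fit(session)
    return est, sel
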