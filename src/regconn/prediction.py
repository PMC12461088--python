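"""Predicting individual differences from FC edge weights.

Subject outcomes are predicted from vectorized upper-triangle edge weights
with ridge regression inside 10-fold cross-validation; the ridge strength
is chosen on each training fold only (efficient leave-one-out nested CV),
and accuracy is the Pearson correlation between pooled out-of-fold
predictions and the actual values. An optional confound is residualized
from the outcome — by default fitted on training subjects only and applied
to the held-out fold, with a flag for the simpler global residualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LinearRegression, RidgeCV
from sklearn.model_selection import KFold


@dataclass
class PredictionReport:
    predicted: np.ndarray
    actual: np.ndarray
    accuracy: float
    fold_assignment: np.ndarray
    chosen_alphas: list
    meta: dict = field(default_factory=dict)


def predict_outcome(
    cohort,
    outcome: str = "outcome",
    confound_to_regress: str | None = None,
    n_folds: int = 10,
    alphas=None,
    rng_seed: int = 0,
    global_confound_removal: bool = False,
) -> PredictionReport:
    """Ridge-regression prediction of a subject covariate from FC edges."""
    if cohort.n_subjects < 20:
        raise ValueError("need >= 20 subjects for nested cross-validated prediction")
    if alphas is None:
        alphas = np.logspace(-3, 4, 15)
    y = cohort.covariates[outcome].to_numpy(float)
    p = cohort.fc_per_subject[0].shape[0]
    iu = np.triu_indices(p, k=1)
    X = np.stack([fc[iu] for fc in cohort.fc_per_subject])

    conf = None
    if confound_to_regress is not None:
        conf = cohort.covariates[confound_to_regress].to_numpy(float).reshape(-1, 1)
        if global_confound_removal:
            y = y - LinearRegression().fit(conf, y).predict(conf)

    n = len(y)
    predicted = np.full(n, np.nan)
    actual = y.astype(float).copy()
    fold_assignment = np.full(n, -1)
    chosen = []
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
    for fold, (tr, te) in enumerate(kf.split(X)):
        y_tr, y_te = y[tr], y[te]
        if conf is not None and not global_confound_removal:
            reg = LinearRegression().fit(conf[tr], y_tr)
            y_tr = y_tr - reg.predict(conf[tr])
            y_te = y_te - reg.predict(conf[te])
            actual[te] = y_te
        model = RidgeCV(alphas=alphas).fit(X[tr], y_tr)
        predicted[te] = model.predict(X[te])
        fold_assignment[te] = fold
        chosen.append(float(model.alpha_))

    accuracy = float(np.corrcoef(predicted, actual)[0, 1])
    return PredictionReport(
        predicted=predicted,
        actual=actual,
        accuracy=accuracy,
        fold_assignment=fold_assignment,
        chosen_alphas=chosen,
        meta={
            "outcome": outcome,
            "confound": confound_to_regress,
            "global_confound_removal": global_confound_removal,
            "seed": rng_seed,
        },
    )
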