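"""Reliability, validity and motion-sensitivity metrics, plus the paired
comparison statistics used in the benchmark tables.

Conventions: connectivity matrices are compared over the strict upper
triangle; percentile/threshold operations act on absolute weights; directed
ground-truth matrices are symmetrized as (W + W^T)/2 before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EvalResult:
    """Per-entity metric values with a summary aggregate."""

    metric: str
    values: np.ndarray
    unit: str = "Pearson r"
    meta: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.values, ddof=1)) if len(self.values) > 1 else 0.0


def upper_triangle(mat: np.ndarray) -> np.ndarray:
    """Vectorized strict upper triangle."""
    mat = np.asarray(mat)
    return mat[np.triu_indices_from(mat, k=1)]


def fisher_z(r):
    return np.arctanh(r)


def inverse_fisher_z(z):
    return np.tanh(z)


def between_session_similarity(fc_a: np.ndarray, fc_b: np.ndarray) -> float:
    """Pearson r of the two matrices' vectorized upper triangles."""
    a, b = upper_triangle(fc_a), upper_triangle(fc_b)
    if a.shape != b.shape:
        raise ValueError("FC matrices must share dimensions")
    return float(np.corrcoef(a, b)[0, 1])


def target_similarity(fc: np.ndarray, target: np.ndarray) -> float:
    """Pearson r between FC and a (symmetrized) target over all edges."""
    target = np.asarray(target, dtype=float)
    if not np.allclose(target, target.T):
        target = (target + target.T) / 2.0
    return between_session_similarity(fc, target)


def icc_1_1(edge_weights: np.ndarray) -> np.ndarray | float:
    """One-way random-effects intraclass correlation, ICC(1,1).

    ``edge_weights`` is subjects x sessions (returns a scalar) or
    subjects x sessions x edges (returns one ICC per edge). Computed from
    one-way ANOVA mean squares as (BMS - WMS) / (BMS + (k - 1) WMS).
    """
    x = np.asarray(edge_weights, dtype=float)
    scalar = x.ndim == 2
    if scalar:
        x = x[:, :, None]
    n, k, _ = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")
    subj_means = x.mean(axis=1)
    grand = x.mean(axis=(0, 1))
    ss_between = k * ((subj_means - grand) ** 2).sum(axis=0)
    ss_within = ((x - subj_means[:, None, :]) ** 2).sum(axis=(0, 1))
    bms = ss_between / (n - 1)
    wms = ss_within / (n * (k - 1))
    denom = bms + (k - 1) * wms
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = (bms - wms) / denom
    icc = np.where(denom == 0, 0.0, icc)
    return float(icc[0]) if scalar else icc


def select_icc_edges(group_mean_fc: list[np.ndarray], percentile: float = 98.0):
    """Edges whose group-mean |weight| reaches the percentile in EVERY method.

    Returns the (row, col) upper-triangle indices of the intersection.
    """
    iu = np.triu_indices_from(np.asarray(group_mean_fc[0]), k=1)
    keep = None
    for fc in group_mean_fc:
        w = np.abs(np.asarray(fc)[iu])
        mask = w >= np.percentile(w, percentile)
        keep = mask if keep is None else (keep & mask)
    return iu[0][keep], iu[1][keep]


def density_threshold(fc: np.ndarray, target_density: float) -> np.ndarray:
    """Keep only the strongest edges at the target density.

    The weakest (1 - density) fraction of absolute weights is zeroed
    (exactly floor(density * n_edges) upper-triangle edges survive; ties
    broken by index order) and the minimum surviving magnitude is then
    subtracted from every surviving magnitude, preserving signs.
    """
    if not (0 < target_density <= 1):
        raise ValueError("target_density must be in (0, 1]")
    fc = np.asarray(fc, dtype=float).copy()
    iu = np.triu_indices_from(fc, k=1)
    w = fc[iu]
    n_keep = int(np.floor(target_density * len(w)))
    out = np.zeros_like(w)
    if n_keep > 0:
        order = np.argsort(-np.abs(w), kind="stable")
        kept = order[:n_keep]
        mags = np.abs(w[kept])
        if target_density < 1:
            mags = mags - mags.min()
        out[kept] = np.sign(w[kept]) * mags
    res = np.zeros_like(fc)
    res[iu] = out
    res = res + res.T
    return res


def _residualize(y: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), confounds])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def qcfc(
    cohort,
    alpha: float = 0.05,
    nonzero_control: bool = False,
    nonzero_abs_threshold: float = 0.01,
    min_subject_fraction: float = 0.8,
) -> dict:
    """Quality control-functional connectivity motion correlations.

    Per edge, the partial Pearson correlation across subjects between edge
    weight and mean relative RMS displacement, conditioned on age and sex;
    significance by Benjamini-Hochberg FDR across the tested edges. With
    ``nonzero_control``, each edge only uses subjects with |w| above the
    threshold and edges retaining fewer than ``min_subject_fraction`` of
    subjects are excluded from the family.
    """
    cov = cohort.covariates
    n = cohort.n_subjects
    if n < 10:
        raise ValueError("need >= 10 subjects for a stable partial correlation")
    motion = cov["motion"].to_numpy(float)
    conf = np.column_stack([cov["age"].to_numpy(float), cov["sex"].to_numpy(float)])
    p = cohort.fc_per_subject[0].shape[0]
    iu = np.triu_indices(p, k=1)
    edges = np.stack([fc[iu] for fc in cohort.fc_per_subject])  # subjects x edges

    n_edges = edges.shape[1]
    r = np.full(n_edges, np.nan)
    pvals = np.full(n_edges, np.nan)
    tested = np.zeros(n_edges, dtype=bool)
    if not nonzero_control:
        mres = _residualize(motion, conf)
        eres = edges - np.column_stack([np.ones(n), conf]) @ np.linalg.lstsq(
            np.column_stack([np.ones(n), conf]), edges, rcond=None
        )[0]
        denom = np.sqrt((mres**2).sum() * (eres**2).sum(axis=0))
        ok = denom > 0
        r[ok] = (eres[:, ok].T @ mres) / denom[ok]
        tested[:] = ok
        df = n - 2 - conf.shape[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = r * np.sqrt(df / (1 - r**2))
        pvals[ok] = 2 * stats.t.sf(np.abs(tstat[ok]), df)
    else:
        min_n = max(10, int(np.ceil(min_subject_fraction * n)))
        for e in range(n_edges):
            mask = np.abs(edges[:, e]) > nonzero_abs_threshold
            if mask.sum() < min_n:
                continue
            mres = _residualize(motion[mask], conf[mask])
            eres = _residualize(edges[mask, e], conf[mask])
            denom = np.sqrt((mres**2).sum() * (eres**2).sum())
            if denom == 0:
                continue
            tested[e] = True
            r[e] = float(mres @ eres / denom)
            df = mask.sum() - 2 - conf.shape[1]
            tstat = r[e] * np.sqrt(df / (1 - r[e] ** 2))
            pvals[e] = 2 * stats.t.sf(abs(tstat), df)

    sig = np.zeros(n_edges, dtype=bool)
    if tested.any():
        rej, _, _, _ = multipletests(pvals[tested], alpha=alpha, method="fdr_bh")
        sig[tested] = rej
    return {
        "r": r,
        "p": pvals,
        "tested": tested,
        "significant": sig,
        "significant_proportion": float(sig.sum() / max(tested.sum(), 1)),
        "median_abs_r": float(np.nanmedian(np.abs(r[tested]))) if tested.any() else np.nan,
        "n_edges_tested": int(tested.sum()),
    }


def compare_dependent_correlations(r_list_a, r_list_b):
    """Two-tailed dependent-samples t-test on Fisher-z transformed r values.

    Returns (t, df, p) plus the mean correlation difference computed by
    transforming to z, subtracting, and transforming back.
    """
    za, zb = fisher_z(np.asarray(r_list_a)), fisher_z(np.asarray(r_list_b))
    if za.shape != zb.shape:
        raise ValueError("paired correlation lists must have equal length")
    mean_dr = float(inverse_fisher_z(np.mean(za - zb)))
    if np.allclose(za, zb):  # zero-variance difference: no effect by definition
        return {"t": 0.0, "df": int(len(za) - 1), "p": 1.0, "mean_delta_r": mean_dr}
    res = stats.ttest_rel(za, zb)
    return {
        "t": float(res.statistic),
        "df": int(len(za) - 1),
        "p": float(res.pvalue),
        "mean_delta_r": mean_dr,
    }


def meng_correlated_correlations(r_a: float, r_b: float, r_ab: float, n: int):
    """Meng-Rosenthal-Rubin z test for two correlations sharing a variable.

    Tests r_a vs r_b where both are correlated with a common third variable
    (their inter-correlation is r_ab). Returns (z, two-tailed p).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    rbar2 = (r_a**2 + r_b**2) / 2.0
    f = min((1 - r_ab) / (2 * (1 - rbar2)), 1.0) if rbar2 < 1 else 1.0
    h = (1 - f * rbar2) / (1 - rbar2) if rbar2 < 1 else 1.0
    z = (fisher_z(r_a) - fisher_z(r_b)) * np.sqrt((n - 3) / (2 * (1 - r_ab) * h))
    p = 2 * stats.norm.sf(abs(z))
    return {"z": float(z), "p": float(p)}


def comparison_table(scores: dict[str, np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise dependent-correlation comparisons with Bonferroni alpha.

    ``scores`` maps method label -> per-entity Pearson r values; the family
    size and adjusted alpha are recorded on every row.
    """
    methods = list(scores)
    rows = []
    pairs = [(a, b) for i, a in enumerate(methods) for b in methods[i + 1 :]]
    adj_alpha = alpha / max(len(pairs), 1)
    for a, b in pairs:
        res = compare_dependent_correlations(scores[a], scores[b])
        rows.append(
            {
                "method_a": a,
                "method_b": b,
                "mean_delta_r": res["mean_delta_r"],
                "t": res["t"],
                "df": res["df"],
                "p": res["p"],
                "n_comparisons": len(pairs),
                "adjusted_alpha": adj_alpha,
                "significant": res["p"] < adj_alpha,
            }
        )
    return pd.DataFrame(rows)
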