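"""Simulation benchmarks: the main reliability/validity comparison and the
data-quantity x noise sweep.

Every stochastic stage derives its seed from the config seed plus integer
keys (network index, session index), so a full run is reproducible and any
output row can be traced back to its generating seeds. Sessions are
independent work units processed in a deterministic order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import HYPERPARAM_ARG, InsufficientDataError, make_estimator
from .metrics import EvalResult, between_session_similarity, comparison_table, target_similarity
from .selection import select_hyperparameter
from .simulate import derive_seed, generate_network, simulate_session

DEFAULT_METHODS = ("pairwise", "partial", "glasso", "gridge", "pcreg")
SWEEP_TIMEPOINTS = (50, 100, 200, 300, 400, 500, 1000, 10000)
SWEEP_NOISE = (0.25, 0.5, 1.0)


@dataclass
class BenchmarkConfig:
    """Design of a simulation benchmark run.

    The full-scale design is 50 networks x 100 sessions x 250 timepoints at
    noise 0.5; the shipped default is a scaled-down 10 x 20 run.
    ``n_sessions_by_method`` optionally caps how many sessions a given
    (expensive) method estimates, without changing what is simulated.
    """

    n_networks: int = 10
    n_sessions: int = 20
    n_timepoints: int = 250
    noise_level: float = 0.5
    methods: tuple = DEFAULT_METHODS
    seed: int = 0
    network_params: dict = field(default_factory=dict)
    n_sessions_by_method: dict = field(default_factory=dict)
    selection_kwargs: dict = field(default_factory=dict)
    scale_factor: str = "reduced (10 networks x 20 sessions vs 50 x 100)"

    def full_scale(self):
        return BenchmarkConfig(
            n_networks=50,
            n_sessions=100,
            methods=self.methods,
            seed=self.seed,
            scale_factor="full (50 networks x 100 sessions)",
        )


def _estimate(method, session, selection_kwargs):
    """(connectivity, selected hyperparameter or None); selection only where needed."""
    if method in HYPERPARAM_ARG:
        sel = select_hyperparameter(session, method, **selection_kwargs)
        est = make_estimator(method, hyperparameter=sel.best_value).fit(session)
        return est.connectivity_, sel.best_value
    return make_estimator(method).fit(session).connectivity_, None


def run_main_benchmark(config: BenchmarkConfig) -> dict:
    """Reliability, validity and individual accuracy of each FC method.

    Per network: between-session similarity of the first two sessions'
    matrices, ground-truth similarity of the session-averaged matrix, and
    ground-truth similarity of the session-1 matrix, against the symmetrized
    generating weights. Returns per-method EvalResults, mean selected
    hyperparameters, Fisher-z paired comparison tables, and a tidy
    per-(network, session, method) trace.
    """
    res = {m: {"between": [], "network_avg": [], "individual": []} for m in config.methods}
    hyper_records = []
    trace = []
    for i in range(config.n_networks):
        net = generate_network(
            rng_seed=derive_seed(config.seed, 0, i), **config.network_params
        )
        truth = net.symmetrized()
        sessions = [
            simulate_session(
                net,
                config.n_timepoints,
                config.noise_level,
                rng_seed=derive_seed(config.seed, 1, i, s),
            )
            for s in range(config.n_sessions)
        ]
        for m in config.methods:
            n_use = min(config.n_sessions_by_method.get(m, config.n_sessions), config.n_sessions)
            fcs = []
            for s in range(n_use):
                fc, hyper = _estimate(m, sessions[s], config.selection_kwargs)
                fcs.append(fc)
                trace.append(
                    {
                        "network": i,
                        "session": s,
                        "method": m,
                        "hyperparameter": hyper,
                        "network_seed": derive_seed(config.seed, 0, i),
                        "session_seed": derive_seed(config.seed, 1, i, s),
                    }
                )
                if hyper is not None:
                    hyper_records.append({"network": i, "session": s, "method": m, "value": hyper})
            if len(fcs) >= 2:
                res[m]["between"].append(between_session_similarity(fcs[0], fcs[1]))
            res[m]["network_avg"].append(
                target_similarity(np.mean(fcs, axis=0), truth)
            )
            res[m]["individual"].append(target_similarity(fcs[0], truth))

    out = {"config": config, "trace": pd.DataFrame(trace)}
    for metric in ("between", "network_avg", "individual"):
        scores = {m: np.asarray(res[m][metric]) for m in config.methods if res[m][metric]}
        out[metric] = {
            m: EvalResult(metric=metric, values=v, meta={"method": m})
            for m, v in scores.items()
        }
        if len(scores) >= 2 and all(len(v) >= 2 for v in scores.values()):
            common = min(len(v) for v in scores.values())
            out[f"{metric}_comparisons"] = comparison_table(
                {m: v[:common] for m, v in scores.items()}
            )
    hyper_df = pd.DataFrame(hyper_records)
    out["mean_hyperparameters"] = (
        hyper_df.groupby("method")["value"].agg(["mean", "std", "count"])
        if len(hyper_df)
        else pd.DataFrame()
    )
    out["hyperparameters"] = hyper_df
    return out


def run_sweep(
    config: BenchmarkConfig,
    timepoints=SWEEP_TIMEPOINTS,
    noise_levels=SWEEP_NOISE,
) -> dict:
    """Individual-accuracy sweep over data quantity and noise level.

    One session per (network, timepoints, noise) condition. Methods that
    cannot run in a condition (partial correlation with T <= p) contribute
    an "insufficient data" record and NaN scores. Also reports, per
    regularized method, the Spearman correlation of condition-mean selected
    hyperparameters with the number of timepoints and with noise level.
    """
    nets = [
        generate_network(rng_seed=derive_seed(config.seed, 2, i), **config.network_params)
        for i in range(config.n_networks)
    ]
    truths = [net.symmetrized() for net in nets]
    rows = []
    for ci, (T, noise) in enumerate(
        (T, nz) for T in timepoints for nz in noise_levels
    ):
        for i, net in enumerate(nets):
            session = simulate_session(
                net, T, noise, rng_seed=derive_seed(config.seed, 3, ci, i)
            )
            for m in config.methods:
                row = {
                    "timepoints": T,
                    "noise": noise,
                    "network": i,
                    "method": m,
                    "hyperparameter": np.nan,
                    "gt_similarity": np.nan,
                    "status": "ok",
                }
                try:
                    fc, hyper = _estimate(m, session, config.selection_kwargs)
                    row["gt_similarity"] = target_similarity(fc, truths[i])
                    if hyper is not None:
                        row["hyperparameter"] = hyper
                except InsufficientDataError as err:
                    row["status"] = f"insufficient data: {err}"
                rows.append(row)
    table = pd.DataFrame(rows)
    cond = (
        table.groupby(["method", "timepoints", "noise"])
        .agg(
            gt_similarity=("gt_similarity", "mean"),
            hyperparameter=("hyperparameter", "mean"),
            n_failed=("status", lambda s: int((s != "ok").sum())),
        )
        .reset_index()
    )
    spearman = {}
    for m in config.methods:
        if m not in HYPERPARAM_ARG:
            continue
        sub = cond[cond["method"] == m]
        rs_T = stats.spearmanr(sub["hyperparameter"], sub["timepoints"])
        rs_noise = stats.spearmanr(sub["hyperparameter"], sub["noise"])
        spearman[m] = {
            "vs_timepoints": {"r": float(rs_T.statistic), "p": float(rs_T.pvalue)},
            "vs_noise": {"r": float(rs_noise.statistic), "p": float(rs_noise.pvalue)},
        }
    return {
        "config": config,
        "table": table,
        "condition_means": cond,
        "hyperparameter_spearman": spearman,
    }
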