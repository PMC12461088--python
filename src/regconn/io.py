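"""Delimited-text readers and writers for networks, sessions, FC matrices
and cohorts. Matrices are stored as TSV with a JSON sidecar carrying the
metadata (module map, seeds, method, hyperparameter, diagnostics).

Orientation: session files store one row per timepoint with a header row of
node identifiers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GroundTruthNetwork, PlantedEffects, SyntheticCohort, TimeSeriesSession


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_network(net: GroundTruthNetwork, path) -> None:
    path = Path(path)
    np.savetxt(path, net.weights, delimiter="\t", fmt="%.12g")
    meta = {
        "module_of": net.module_of.tolist(),
        "inhibitory_module": int(net.inhibitory_module),
        "meta": {k: v for k, v in net.meta.items() if k != "attachment_log"},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_network(path) -> GroundTruthNetwork:
    path = Path(path)
    W = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta = json.loads(_sidecar(path).read_text())
    return GroundTruthNetwork(
        W,
        np.asarray(meta["module_of"], dtype=int),
        int(meta["inhibitory_module"]),
        meta.get("meta", {}),
    )


def write_session(session: TimeSeriesSession, path) -> None:
    path = Path(path)
    cols = [f"node{j:03d}" for j in range(session.n_nodes)]
    header = "\t".join(cols)
    np.savetxt(path, session.data, delimiter="\t", fmt="%.12g", header=header, comments="")
    meta = {"noise_level": session.noise_level, "seed": int(session.seed), "tr": session.tr}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_session(path) -> TimeSeriesSession:
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    return TimeSeriesSession(
        data,
        noise_level=meta.get("noise_level", float("nan")),
        seed=meta.get("seed", -1),
        tr=meta.get("tr"),
    )


def write_fc(fc: np.ndarray, path, method: str = "", hyperparameter=None, source: str = "",
             diagnostics: dict | None = None) -> None:
    path = Path(path)
    np.savetxt(path, fc, delimiter="\t", fmt="%.12g")
    meta = {
        "method": method,
        "hyperparameter": hyperparameter,
        "source": source,
        "diagnostics": diagnostics or {},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_fc(path):
    path = Path(path)
    fc = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    return fc, meta


def write_cohort(cohort: SyntheticCohort, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s, fc in enumerate(cohort.fc_per_subject):
        np.savetxt(directory / f"fc_sub-{s:04d}.tsv", fc, delimiter="\t", fmt="%.12g")
    cohort.covariates.to_csv(directory / "covariates.tsv", sep="\t", index=False)
    planted = {
        "motion_edges": [list(map(int, e)) for e in cohort.planted.motion_edges],
        "motion_effect_size": cohort.planted.motion_effect_size,
        "outcome_edges": [list(map(int, e)) for e in cohort.planted.outcome_edges],
        "outcome_effect_size": cohort.planted.outcome_effect_size,
        "outcome_noise_sd": cohort.planted.outcome_noise_sd,
        "subject_jitter_sd": cohort.planted.subject_jitter_sd,
        "edge_noise_sd": cohort.planted.edge_noise_sd,
        "meta": cohort.meta,
    }
    (directory / "planted.json").write_text(json.dumps(planted, indent=1))


def read_cohort(directory) -> SyntheticCohort:
    directory = Path(directory)
    covariates = pd.read_csv(directory / "covariates.tsv", sep="\t")
    fcs = [
        np.loadtxt(f, delimiter="\t", ndmin=2)
        for f in sorted(directory.glob("fc_sub-*.tsv"))
    ]
    meta = {}
    planted = PlantedEffects()
    pfile = directory / "planted.json"
    if pfile.exists():
        d = json.loads(pfile.read_text())
        meta = d.pop("meta", {})
        planted = PlantedEffects(
            motion_edges=[tuple(e) for e in d["motion_edges"]],
            motion_effect_size=d["motion_effect_size"],
            outcome_edges=[tuple(e) for e in d["outcome_edges"]],
            outcome_effect_size=d["outcome_effect_size"],
            outcome_noise_sd=d["outcome_noise_sd"],
            subject_jitter_sd=d["subject_jitter_sd"],
            edge_noise_sd=d["edge_noise_sd"],
        )
    return SyntheticCohort(fcs, covariates, planted, meta=meta)
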