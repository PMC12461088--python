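"""Ground-truth network and time-series simulation.

Networks are directed, weighted, modular and roughly scale-free: each module
grows by preferential attachment from a fully connected seed clique, a small
number of inter-modular edges is then added (again degree-preferentially),
weights are drawn per directed edge, one module is made inhibitory, and the
whole matrix is normalized so that linear mixing is stable.

Node activity follows the linear structural model ``X = W X + E`` solved as
``X = (I - W)^{-1} E`` with i.i.d. standard-normal intrinsic terms, plus
Gaussian measurement noise scaled relative to each node's signal amplitude.
An optional variant replaces the Gaussian intrinsic terms with Poisson
up/down state trains convolved with a canonical haemodynamic response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve
from scipy.stats import gamma as gamma_dist


def derive_seed(seed: int, *keys: int) -> int:
    """Deterministically derive a child seed (< 2**31) from a root seed and keys."""
    ss = np.random.SeedSequence((int(seed),) + tuple(int(k) for k in keys))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class GroundTruthNetwork:
    """Directed weighted adjacency with module labels.

    ``weights[i, j]`` is the influence of node ``j`` on node ``i`` (an input
    to ``i``), so row sums of ``|weights|`` are summed absolute inputs.
    """

    weights: np.ndarray
    module_of: np.ndarray
    inhibitory_module: int
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def symmetrized(self) -> np.ndarray:
        """Undirected version: arithmetic mean of the two directed weights."""
        return (self.weights + self.weights.T) / 2.0

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.weights))))

    def edge_counts(self) -> tuple[int, int]:
        """(intra-modular, extra-modular) directed nonzero edge counts."""
        nz = self.weights != 0
        same = self.module_of[:, None] == self.module_of[None, :]
        return int(np.sum(nz & same)), int(np.sum(nz & ~same))


@dataclass
class TimeSeriesSession:
    """Timepoints x nodes activity matrix with sampling metadata."""

    data: np.ndarray
    noise_level: float
    seed: int
    tr: float | None = None

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass
class PlantedEffects:
    """Effect specification for synthetic cohorts.

    motion_edges / outcome_edges are (i, j) upper-triangle index pairs that
    carry the planted motion artifact / outcome signal; effect sizes are on
    the scale of standardized covariates.
    """

    motion_edges: Sequence[tuple[int, int]] = ()
    motion_effect_size: float = 0.0
    outcome_edges: Sequence[tuple[int, int]] = ()
    outcome_effect_size: float = 0.0
    outcome_noise_sd: float = 1.0
    subject_jitter_sd: float = 0.05
    edge_noise_sd: float = 0.05


@dataclass
class SyntheticCohort:
    """Per-subject FC matrices plus covariates and the planted ground truth."""

    fc_per_subject: list[np.ndarray]
    covariates: "pandas.DataFrame"  # noqa: F821 - imported lazily in generate_cohort
    planted: PlantedEffects
    meta: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.fc_per_subject)


def _grow_module(rng: np.random.Generator, module_size: int, growth_edges: int):
    """Preferential-attachment growth of one module's undirected skeleton.

    Starts from a fully connected clique of ``growth_edges`` nodes; every
    added node attaches ``growth_edges`` distinct edges to existing nodes
    with probability proportional to current degree k_i / sum_j k_j.
    Returns (edges, attachment log) with edges as local (a, b) index pairs.
    """
    m = growth_edges
    if module_size < m:
        raise ValueError("module_size must be at least growth_edges")
    edges = [(a, b) for a in range(m) for b in range(a + 1, m)]
    degree = np.zeros(module_size)
    degree[:m] = m - 1
    attach_log = []  # (degrees snapshot, chosen node) pairs, for auditing
    for new in range(m, module_size):
        existing = np.arange(new)
        avail = np.ones(new, dtype=bool)
        for _ in range(m):
            probs = degree[existing] * avail
            total = probs.sum()
            if total <= 0:  # all remaining nodes isolated: uniform fallback
                probs = avail.astype(float)
                total = probs.sum()
            probs = probs / total
            target = int(rng.choice(existing, p=probs))
            attach_log.append((degree[existing].copy(), avail.copy(), target))
            avail[target] = False
            edges.append((target, new))
            degree[target] += 1
            degree[new] += 1
    return edges, attach_log


def generate_network(
    p: int = 100,
    n_modules: int = 5,
    module_size: int = 20,
    growth_edges: int = 4,
    extra_modular_target: int = 186,
    intra_mean: float = 1.0,
    extra_mean: float = 0.5,
    weight_sd: float = 1.0,
    scale: float = 0.6,
    rng_seed: int = 0,
    max_attempts: int = 100,
    _collect_attachment_log: bool = False,
) -> GroundTruthNetwork:
    """Generate a modular preferential-attachment ground-truth network.

    The binary skeleton is undirected (every structural edge is realized in
    both directions); the two directed weights are drawn independently from
    Normal(intra_mean or extra_mean, weight_sd). One randomly chosen module
    is inhibitory: every extra-modular weight into or out of it is negated.
    All weights are divided by the network mean of summed absolute inputs
    per node and multiplied by ``scale``; generation is retried with fresh
    draws until the spectral radius is strictly below 1.
    """
    if p != n_modules * module_size:
        raise ValueError("p must equal n_modules * module_size")
    if not (module_size > growth_edges >= 1):
        raise ValueError("need module_size > growth_edges >= 1")
    if extra_modular_target % 2 != 0:
        raise ValueError("extra_modular_target counts directed edges and must be even")
    n_pairs_between = (p * (p - 1) - n_modules * module_size * (module_size - 1)) // 2
    if extra_modular_target // 2 > n_pairs_between:
        raise ValueError("extra_modular_target exceeds available inter-modular pairs")

    rng = np.random.default_rng(rng_seed)
    for attempt in range(1, max_attempts + 1):
        module_of = np.repeat(np.arange(n_modules), module_size)
        undirected: list[tuple[int, int]] = []
        attach_logs = []
        for mod in range(n_modules):
            offset = mod * module_size
            edges, log = _grow_module(rng, module_size, growth_edges)
            undirected.extend((offset + a, offset + b) for a, b in edges)
            if _collect_attachment_log:
                attach_logs.append(log)

        adj = np.zeros((p, p), dtype=bool)
        for a, b in undirected:
            adj[a, b] = adj[b, a] = True
        degree = adj.sum(1).astype(float)

        # Inter-modular edges: both endpoints degree-preferential; reject
        # self-pairs, intra-module pairs and duplicates, then resample.
        n_extra = extra_modular_target // 2
        added = 0
        while added < n_extra:
            probs = degree / degree.sum()
            a = int(rng.choice(p, p=probs))
            probs = degree / degree.sum()
            b = int(rng.choice(p, p=probs))
            if a == b or module_of[a] == module_of[b] or adj[a, b]:
                continue
            adj[a, b] = adj[b, a] = True
            degree[a] += 1
            degree[b] += 1
            undirected.append((a, b))
            added += 1

        same_module = module_of[:, None] == module_of[None, :]
        W = np.zeros((p, p))
        directed = adj & ~np.eye(p, dtype=bool)
        means = np.where(same_module, intra_mean, extra_mean)
        W[directed] = rng.normal(means[directed], weight_sd)

        inhibitory = int(rng.integers(n_modules))
        inhib_nodes = module_of == inhibitory
        extra_mask = directed & ~same_module
        touches = inhib_nodes[:, None] | inhib_nodes[None, :]
        W[extra_mask & touches] *= -1.0

        # network mean of (signed) summed inputs per node; robustly positive
        # because excitatory mass dominates, but guard the degenerate tail
        divisor = W.sum(axis=1).mean()
        if divisor <= 0.1:
            continue
        W /= divisor
        W *= scale

        radius = float(np.max(np.abs(np.linalg.eigvals(W))))
        if radius < 1.0:
            meta = {
                "p": p,
                "n_modules": n_modules,
                "module_size": module_size,
                "growth_edges": growth_edges,
                "extra_modular_target": extra_modular_target,
                "intra_mean": intra_mean,
                "extra_mean": extra_mean,
                "weight_sd": weight_sd,
                "scale": scale,
                "seed": rng_seed,
                "attempts": attempt,
                "spectral_radius": radius,
            }
            net = GroundTruthNetwork(W, module_of, inhibitory, meta)
            if _collect_attachment_log:
                net.meta["attachment_log"] = attach_logs
            return net
    raise RuntimeError(
        f"failed to generate a stable network in {max_attempts} attempts"
    )


def simulate_session(
    net: GroundTruthNetwork,
    n_timepoints: int = 250,
    noise_level: float = 0.5,
    rng_seed: int = 0,
) -> TimeSeriesSession:
    """Simulate one session from the linear model X = (I - W)^{-1} E.

    ``E`` is T x p i.i.d. standard normal; measurement noise is Gaussian with
    per-node SD equal to ``noise_level`` times the noiseless series SD.
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    W = net.weights
    p = W.shape[0]
    if net.spectral_radius() >= 1.0:
        raise ValueError("spectral radius of W must be < 1 for a stable solution")
    rng = np.random.default_rng(rng_seed)
    E = rng.standard_normal((n_timepoints, p))
    # rows of X solve x (I - W)^T = e  <=>  X = E (I - W)^{-T}
    X = np.linalg.solve(np.eye(p) - W, E.T).T
    if noise_level > 0:
        X = X + rng.standard_normal(X.shape) * (noise_level * X.std(axis=0))
    return TimeSeriesSession(X, noise_level=noise_level, seed=rng_seed)


def _canonical_hrf(dt: float, duration: float = 32.0) -> np.ndarray:
    """Double-gamma haemodynamic response (peak 6 s, undershoot 16 s, ratio 1/6)."""
    t = np.arange(0, duration, dt)
    h = gamma_dist.pdf(t, 7.0) - gamma_dist.pdf(t, 17.0) / 6.0
    return h / h.max()


def _updown_train(
    rng: np.random.Generator, n_steps: int, dt: float, up_mean_s: float, down_mean_s: float
) -> np.ndarray:
    """Binary up/down state train with exponential holding times."""
    out = np.empty(n_steps)
    pos = 0
    # start in a state drawn from the stationary occupancy of the renewal process
    up = rng.random() < up_mean_s / (up_mean_s + down_mean_s)
    while pos < n_steps:
        mean = up_mean_s if up else down_mean_s
        length = max(1, int(round(rng.exponential(mean) / dt)))
        out[pos : pos + length] = 1.0 if up else 0.0
        pos += length
        up = not up
    return out


def simulate_hrf_session(
    net: GroundTruthNetwork,
    duration_s: float = 500.0,
    dt: float = 0.05,
    tr: float = 2.0,
    up_mean_s: float = 2.5,
    down_mean_s: float = 10.0,
    neural_noise_frac: float = 0.05,
    noise_level: float = 0.5,
    rng_seed: int = 0,
) -> TimeSeriesSession:
    """Simulate a haemodynamic session from Poisson up/down neural states.

    Per-node binary state trains (exponential holding times) receive additive
    neural noise (SD = ``neural_noise_frac`` x the up/down state difference),
    are mixed through the network via (I - W)^{-1} at every fine timestep,
    convolved with a canonical double-gamma response, downsampled from ``dt``
    to ``tr``, and finally given measurement noise as in `simulate_session`.
    """
    stride = tr / dt
    if abs(stride - round(stride)) > 1e-9:
        raise ValueError("dt must divide tr")
    stride = int(round(stride))
    n_steps = int(round(duration_s / dt))
    if n_steps < stride:
        raise ValueError("duration_s must cover at least one tr")
    W = net.weights
    p = W.shape[0]
    rng = np.random.default_rng(rng_seed)
    E = np.empty((n_steps, p))
    for node in range(p):
        E[:, node] = _updown_train(rng, n_steps, dt, up_mean_s, down_mean_s)
    if neural_noise_frac > 0:
        E = E + rng.standard_normal(E.shape) * neural_noise_frac
    X = np.linalg.solve(np.eye(p) - W, E.T).T
    hrf = _canonical_hrf(dt)
    X = fftconvolve(X, hrf[:, None], axes=0)[:n_steps]
    X = X[::stride][: n_steps // stride]  # floor(duration_s / tr) samples
    if noise_level > 0:
        X = X + rng.standard_normal(X.shape) * (noise_level * X.std(axis=0))
    return TimeSeriesSession(X, noise_level=noise_level, seed=rng_seed, tr=tr)


def generate_cohort(
    base_net: GroundTruthNetwork,
    n_subjects: int,
    planted: PlantedEffects | None = None,
    rng_seed: int = 0,
    mode: str = "direct",
    n_timepoints: int = 250,
    noise_level: float = 0.5,
    fc_estimator=None,
) -> SyntheticCohort:
    """Generate a synthetic cohort of FC matrices with planted covariate effects.

    Each subject's true network is the base network with Gaussian jitter on
    the existing support. In ``mode="direct"`` the subject FC is the
    symmetrized true network plus edgewise measurement noise (fast, exact
    planted effects); in ``mode="session"`` a session is simulated from the
    jittered network and FC is estimated with ``fc_estimator`` (defaults to
    pairwise correlation). Motion artifacts are then added to the designated
    FC edges in proportion to the subject's standardized motion, and the
    outcome is built from the designated true edge weights plus noise.
    """
    import pandas as pd

    from .estimators import PairwiseCorrelation

    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    planted = planted or PlantedEffects()
    if planted.outcome_effect_size != 0 and len(planted.outcome_edges) == 0:
        raise ValueError("outcome effect planted but no outcome edges designated")
    rng = np.random.default_rng(rng_seed)
    W = base_net.weights
    support = W != 0
    # planted outcome edges carry real individual differences even when they
    # fall outside the structural support
    for i, j in planted.outcome_edges:
        support[i, j] = support[j, i] = True
    p = W.shape[0]

    age = rng.uniform(36, 100, n_subjects)
    sex = rng.integers(0, 2, n_subjects).astype(float)
    motion = rng.gamma(shape=2.0, scale=0.05, size=n_subjects)  # mean RMS ~0.1 mm
    motion_z = (motion - motion.mean()) / motion.std()

    fcs = []
    true_edge_signal = np.zeros(n_subjects)
    for s in range(n_subjects):
        Ws = W.copy()
        Ws[support] += rng.normal(0.0, planted.subject_jitter_sd, support.sum())
        sym = (Ws + Ws.T) / 2.0
        if mode == "direct":
            fc = sym + rng.normal(0.0, planted.edge_noise_sd, (p, p))
            fc = (fc + fc.T) / 2.0
            np.fill_diagonal(fc, 0.0)
        elif mode == "session":
            sub_net = GroundTruthNetwork(Ws, base_net.module_of, base_net.inhibitory_module)
            if sub_net.spectral_radius() >= 1.0:
                Ws = W  # fall back to the unjittered net if jitter destabilized it
                sub_net = base_net
                sym = (Ws + Ws.T) / 2.0
            sess = simulate_session(
                sub_net, n_timepoints, noise_level, derive_seed(rng_seed, 1, s)
            )
            est = fc_estimator if fc_estimator is not None else PairwiseCorrelation()
            fc = est.fit(sess.data).connectivity_.copy()
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for i, j in planted.motion_edges:
            bump = planted.motion_effect_size * motion_z[s]
            fc[i, j] += bump
            fc[j, i] += bump
        fcs.append(fc)
        if planted.outcome_edges:
            true_edge_signal[s] = np.mean([sym[i, j] for i, j in planted.outcome_edges])

    if planted.outcome_edges and planted.outcome_effect_size != 0:
        sig_sd = true_edge_signal.std()
        if sig_sd == 0:
            raise ValueError("degenerate effect spec: planted edge signal has zero variance")
        signal = (true_edge_signal - true_edge_signal.mean()) / sig_sd
        outcome = planted.outcome_effect_size * signal + rng.normal(
            0.0, planted.outcome_noise_sd, n_subjects
        )
    else:
        outcome = rng.normal(0.0, planted.outcome_noise_sd, n_subjects)

    covariates = pd.DataFrame(
        {
            "subject": [f"sub-{s:04d}" for s in range(n_subjects)],
            "motion": motion,
            "age": age,
            "sex": sex,
            "outcome": outcome,
        }
    )
    return SyntheticCohort(
        fcs,
        covariates,
        planted,
        meta={"seed": rng_seed, "mode": mode, "base_seed": base_net.meta.get("seed")},
    )
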