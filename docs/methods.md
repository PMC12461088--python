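# Methods

## Ground-truth networks

Networks have `p = 100` nodes in 5 modules of 20 (defaults; all counts are
parameters). Each module's undirected skeleton grows by preferential
attachment from a fully connected seed clique of `m = 4` nodes: every added
node brings `m` edges that attach to distinct existing nodes with
probability `k_i / Σ_j k_j` (degree-proportional, renormalized after each
draw). This yields exactly `C(m,2) + (s − m)·m` undirected intra-modular
edges per module — 70 for the defaults, hence 700 directed intra-modular
edges per network, every run. Inter-modular edges are then added one
undirected pair at a time, both endpoints drawn degree-proportionally from
the whole network, rejecting self-pairs, intra-module pairs and duplicates,
until the target directed count (default 186) is reached. The double-density
variant (seed 8, `m = 8`, scale 0.65) has 124 undirected intra edges per
module, i.e. 1240 directed — about 1.8x the default.

Each directed edge gets an independent Normal weight (intra-modular mean 1,
inter-modular mean 0.5, SD 1; the two directions of a structural edge are
drawn independently). One module, chosen at random, is inhibitory: all
inter-modular weights into or out of it are negated. Finally all weights
are divided by the network mean of the (signed) summed inputs per node and
multiplied by 0.6. Two interpretations of that normalizer are possible —
signed sums or absolute sums; we use the signed network mean, which is the
literal reading, is robustly positive (≈ 7, since excitatory mass
dominates), and produces the operating regime (spectral radius ≈ 0.8) in
which the estimator reliability/validity levels reproduce; absolute-sum
normalization yields a much weaker coupling regime (radius ≈ 0.58) with
qualitatively different reliability. Networks whose spectral radius reaches
1 are discarded and regenerated (attempt count recorded in `meta`); in
practice the first draw almost always passes.

## Time-series model

Sessions are `T x p` matrices from the linear structural model
`X = W X + E` with i.i.d. standard-normal intrinsic terms, solved per
timepoint as `x = (I − W)^{-1} e` (in row convention `X = E (I − W)^{-T}`).
The noiseless node covariance is therefore `(I − W)^{-1} (I − W)^{-T}`.
Measurement noise is Gaussian per node with SD = `noise_level` x that
node's noiseless SD (default 0.5, i.e. noise at half the signal
amplitude). Note the population precision of `X` is `(I − W)^T (I − W)`:
its support strictly contains the symmetrized structural skeleton (pairs
with a common child acquire "moralization" fill-in), which is why estimator
consistency is judged against the population partial-correlation matrix
rather than the raw skeleton.

The haemodynamic variant replaces `E` with binary up/down state trains per
node (exponential holding times, means 2.5 s up / 10 s down, so the
stationary up-state fraction is 0.2) sampled at `dt = 0.05 s`, adds neural
noise (SD = 5% of the state difference), mixes through `(I − W)^{-1}` at
every fine step, convolves with a double-gamma response (modes at 6 s and
16 s, undershoot ratio 1/6 — the conventional shape, since only "canonical"
is specified anywhere), downsamples to `tr = 2 s` (floor(duration/tr)
samples), and adds measurement noise last.

## Estimators

All five estimators z-score each node's series (population SD) and, except
PC regression, operate on the sample correlation matrix with the
T-denominator convention (consistent with z-scoring; for these data
covariance = correlation). Outputs are exactly symmetric with zero
diagonal; pairwise and partial entries are bounded in [−1, 1]. Estimators
are scikit-learn `BaseEstimator`s (`fit`, `get_params`/`set_params`,
`connectivity_`, a shared `score` implementing the held-out R² criterion),
so they clone and compose with sklearn tooling.

- **Pairwise**: Pearson correlation per node pair.
- **Partial**: precision `P` from inverting the correlation matrix;
  `r_ij|C = −P_ij / sqrt(P_ii P_jj)`. Requires `T > p`; otherwise an
  `InsufficientDataError` is raised (this is the failure mode the sweep
  records at 50 timepoints).
- **Graphical lasso**: maximizes the Gaussian log-likelihood minus
  `λ₁ Σ_{i≠j} |P_ij|` — the penalty excludes the diagonal. Solved by
  proximal gradient descent with Barzilai–Borwein steps and a backtracking
  line search that preserves positive definiteness; convergence when the
  max absolute iterate change falls below 1e-5 (final fits; 3e-4 inside
  CV, where only the R² ranking of nearby penalties matters — selections
  are verified insensitive to this tolerance down to 1e-4), capped at 10⁴
  iterations, both configurable, diagnostics recorded.
  The solver is validated in the tests against scikit-learn's
  graphical_lasso and against a generic split-variable L-BFGS-B solution of
  the same objective (agreement ≤ 1e-4 on 5-node problems).
- **Graphical ridge**: same likelihood with `λ₂ Σ_{i≠j} P_ij²`. The
  stationarity condition `P^{-1} = (S − 2λ₂ diag(P)) + 2λ₂ P` is solved
  exactly in the eigenbasis of the shifted covariance for a fixed diagonal
  and iterated on the diagonal with componentwise Aitken extrapolation
  (typically < 15 eigendecompositions). Note this is the penalty as
  written; packaged "ridge precision" estimators often solve a different
  objective (full Frobenius penalty toward a target), so their λ values are
  not comparable even though the selected-λ FC estimates behave similarly.
- **PC regression**: per target node, PCA of the other nodes' series
  (columns already z-scored; components ordered by variance, sign fixed by
  the largest-magnitude loading), regression of the target on the top-n
  scores without intercept, coefficients back-projected to per-node
  weights; the assembled matrix is averaged with its transpose.

## Hyperparameter selection

10 contiguous timepoint folds (deterministic given T); the session is
z-scored once, not per split. For each candidate value, the FC matrix is
fit on 9/10 of the data and each node's held-out activity is predicted as
the FC-weighted sum of the other nodes' concurrent held-out activity;
fit = `1 − SS_res/SS_tot` with no refit intercept, averaged over nodes and
folds. Identical harness code scores every method. Grids: λ₁ from 0.005 to
0.15 in steps of 0.005, λ₂ from 0.1 to 3.0 in steps of 0.1, PCs from 10 to
p−1 in steps of 5 (never below 10). A maximum on the boundary of the range
triggers expansion by one grid-width (up to 10 times, logged). Ties break
toward less regularization (smaller λ, more PCs).

Rather than evaluating every grid value with every fold, the default search
exploits the smooth unimodality of the R² profile: a single-fold pilot
descends a coarse subsample (every 5th value) from the sparse end until the
peak is bracketed, and all folds then evaluate the fine-step window around
the pilot anchor, walking outward whenever the full-fold argmax touches the
window edge; iterative solvers warm-start from the nearest solved value.
Selected values live on the same fine lattice, and `search="full"`
recovers the exhaustive scan (the tests assert both agree). Training-fold
correlation matrices are formed by Gram-matrix downdates, and the
PC-regression path reuses one eigendecomposition of the training Gram per
(fold, target) for every PC count at once.

## Evaluation metrics

- Between-session similarity: Pearson r of vectorized strict upper
  triangles of two sessions' FC.
- Ground-truth / target similarity: same, against the symmetrized
  ((W + Wᵀ)/2) generating weights, all edges included.
- ICC(1,1): one-way random-effects `(BMS − WMS) / (BMS + (k−1) WMS)` per
  edge; the companion edge selector keeps edges whose group-mean |weight|
  reaches the 98th percentile in every method (sparse methods would
  otherwise be penalized for their structural zeros).
- Density thresholding: keeps the top `floor(density x n_edges)` absolute
  weights (ties by index), subtracts the minimum surviving magnitude,
  preserves signs. Thresholds operate on absolute weights throughout so
  strong negative edges are not discarded asymmetrically.
- QC-FC: per-edge partial correlation between subjects' edge weights and
  mean motion, conditioning on age and sex (residualization form, which the
  tests pin to the direct formula at 1e-10), BH-FDR across edges; the
  nonzero-edge control drops subjects with |w| ≤ .01 per edge and excludes
  edges retaining < 80% of subjects from the family.
- Comparison statistics: two-tailed dependent t-tests on Fisher-z
  transformed correlations (zero-variance differences are reported as
  t = 0, p = 1 rather than NaN), with family size and Bonferroni-adjusted
  α recorded on every table row; Meng–Rosenthal–Rubin z for correlated
  correlations sharing a variable.

## Activity flow and individual differences

Activity flow predicts `Â_j = Σ_{i≠j} A_i W_ij` (the zero FC diagonal
enforces i ≠ j); accuracy is the Pearson r of predicted vs actual pooled
across nodes and conditions. Covariate prediction vectorizes the FC upper
triangle, fits ridge regression in outer 10-fold CV (shuffled, seeded) with
the ridge strength chosen per training fold by efficient leave-one-out
selection over a log grid 1e-3…1e4, pools out-of-fold predictions, and
reports their Pearson r with the actuals. Confound removal is fitted on
training folds and applied to test folds by default (leakage-safe); a flag
restores plain global residualization. Pooled CV correlations are
negatively biased under the null (fold intercepts anti-correlate with
held-out outcomes), so the permutation suite checks that null accuracies
straddle zero from below and sit far beneath planted-signal accuracies, not
that they average exactly zero.

## Synthetic cohorts

`generate_cohort` emulates a subject sample: per subject the base network
is jittered on its support (SD 0.05 by default) plus any planted outcome
edges; FC is either the symmetrized true network plus edgewise noise
("direct", exact planted effects, fast) or estimated from a simulated
session ("session"). Motion (gamma-distributed mean RMS displacement,
~0.1 mm), age (uniform 36–100) and sex are drawn independently; planted
motion artifacts add `effect x standardized motion` to designated FC edges,
and the outcome is a standardized combination of designated true edge
weights plus Gaussian noise. The cohort captures edge-level individual
differences and confound structure but not spatial autocorrelation,
distance-dependent motion artifacts, or session-to-session drift — cohort
metrics validated here demonstrate procedural correctness, not empirical
effect sizes.

## Benchmark scale and runtime choices

The published design (50 networks x 100 sessions) is reproduced at reduced
scale: 5 networks for session-averaged validity (100 sessions averaged for
the un-regularized estimators, 25 for the regularized ones), 10 networks
for individual accuracy, reliability, and each sweep condition. At these
sizes the full acceptance run completes in roughly 10–15 minutes on one
CPU while keeping between-network SEs a few times smaller than the
published between-method gaps. Every stage derives its seed from the run
seed plus integer keys (network index, session index), so runs are
bit-reproducible up to solver-tolerance float noise and any output row can
be traced to its generating seeds.

## Known limitations

- The linear, contemporaneous generative model has no haemodynamic lag
  structure except in the explicit HRF variant, and no subject-level
  physiological confounds.
- Graphical-ridge λ values are specific to the off-diagonal-penalty
  objective (see above) and should not be compared across packages.
- The pilot search assumes a unimodal held-out R² profile; pathological
  profiles fall back gracefully (boundary flags, `search="full"`), but
  multimodal profiles could in principle select a local optimum.
- Empirical MRI processing (parcellation, nuisance regression, diffusion
  tractography, psychometric factor scores) is out of scope; structural
  matrices and activation patterns are consumed as provided files.
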