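# regconn

Regularized partial-correlation functional connectivity (FC): five
estimators with cross-validated hyperparameter selection, a ground-truth
network simulator, and the reliability/validity evaluation battery built
around them.

## The problem

Pairwise Pearson correlation — the standard way of estimating FC between
brain regions — is reliable but confounded: two regions driven by a common
third region appear connected even when no direct connection exists.
Partial correlation removes such confounds by conditioning each pair on all
other regions (inverting the correlation matrix to get the precision matrix
`P`, then `r_ij|C = -P_ij / sqrt(P_ii P_jj)`), but with realistic scan
lengths the inversion overfits catastrophically: estimates barely replicate
between sessions. Regularization recovers that lost reliability while
keeping the confound correction. This package implements and evaluates the
candidates:

| method     | estimator                      | regularization                      |
| ---------- | ------------------------------ | ----------------------------------- |
| `pairwise` | Pearson correlation            | none                                |
| `partial`  | inverse correlation matrix     | none                                |
| `glasso`   | graphical lasso                | L1 on off-diagonal precision, λ₁    |
| `gridge`   | graphical ridge                | squared L2 on off-diagonal precision, λ₂ |
| `pcreg`    | principal-components regression | top-n PCs per target node          |

Hyperparameters are chosen per session by 10-fold cross-validation within
the time series: each node's held-out activity is predicted as the
FC-weighted sum of the other nodes' concurrent activity, and the value
maximizing mean held-out R² wins. The criterion is identical for every
method, so no method is favored by its own goodness-of-fit convention.

Because no empirical ground truth exists for FC, validity is measured on
simulated data: modular, roughly scale-free directed networks `W` (5
preferential-attachment modules, one inhibitory) generate activity through
the linear model `X = W X + E`, solved as `X = (I − W)⁻¹ E`, plus
measurement noise. Estimated FC is then scored against the known,
symmetrized `W`.

## Worked example

```python
import regconn as rc

net = rc.generate_network(rng_seed=1)          # 100 nodes, 5 modules
print(net.edge_counts())                       # (700, 186) directed edges

sess = rc.simulate_session(net, n_timepoints=250, noise_level=0.5, rng_seed=3)

sel = rc.select_hyperparameter(sess, "glasso")
print(round(sel.best_value, 3))                # 0.1  (CV-selected lambda-1)

fc_glasso = rc.GraphicalLassoFC(lambda1=sel.best_value).fit(sess).connectivity_
fc_partial = rc.partial_correlation(sess)
truth = net.symmetrized()
print(round(rc.target_similarity(fc_glasso, truth), 3))   # 0.812
print(round(rc.target_similarity(fc_partial, truth), 3))  # 0.4
```

The two similarity numbers show the point of the package in miniature: from
a single 250-timepoint session, regularized partial correlation recovers
the generating network about twice as well (r ≈ 0.81) as the unregularized
inversion (r ≈ 0.40), because the L1 penalty suppresses the sampling noise
that dominates the raw precision estimate.

A shell interface wraps the same functions:

```bash
regconn simulate network --seed 1 --out net.tsv
regconn simulate session --network net.tsv --timepoints 250 --seed 3 --out sess.tsv
regconn estimate --method glasso --param auto --in sess.tsv --out fc.tsv
regconn bench main --seed 0 --out bench_out/
```

## Beyond the benchmarks

The package also ships the surrounding evaluation toolkit used on cohort
data: edgewise ICC(1,1) reliability with top-percentile edge selection,
density-matched thresholding for comparisons against sparse structural
references, QC-FC motion-confound screening with BH-FDR, activity-flow
mapping (`Â_j = Σ_{i≠j} A_i W_ij`), ridge prediction of subject covariates
from FC edges with nested CV, and a synthetic-cohort generator with planted
covariate effects for validating all of the above.
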