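# hgptime

Hierarchical Gaussian process models for replicated gene-expression
time series: regression across replicates and experiments with
arbitrary, irregular time sampling; an efficient marginal likelihood
for clusters of genes; greedy agglomerative clustering with EM
hyperparameter updates; and missing-data imputation.

## Who this is for

Time-course expression experiments (microarray or sequencing) are
usually run in several biological replicates with ragged, irregular
sampling — no replicate need contain every time point. Simply averaging
replicates discards the temporal structure of the biological variation
between them. `hgptime` models that structure directly, for analysts who
want to: separate shared signal from replicate variation and noise,
rank genes by reproducible temporal signal, cluster genes by shared
latent profiles, or impute systematically missing arrays.

## The model

A gene's underlying profile is a draw from a zero-mean GP, and each
replicate deviates from it by a further GP draw, plus iid noise:

    g_n(t)  ~ GP(0, k_g),      f_nr(t) ~ GP(g_n(t), k_f),
    y_nr(t) = f_nr(t) + eps,   eps ~ N(0, beta)

with squared-exponential kernels k(t, t') = alpha exp(-gamma (t-t')^2)
per layer. Marginally, covariances add along shared ancestry: two
observations in the same replicate have covariance k_g + k_f (+ beta
on the diagonal); in different replicates of one gene, k_g. The
hierarchy extends arbitrarily — an experiment layer for data fusion, or
a cluster layer h_i(t) above the genes:

    h_i(t) ~ GP(0, k_h),   g_n(t) ~ GP(h_i(t), k_g),   f_nr(t) ~ GP(g_n(t), k_f).

Hyperparameters are set by type-II maximum likelihood (L-BFGS on
log-parameters with analytic gradients). For a cluster of N genes all
measured on one layout of D coordinates, integrating out the shared
profile reduces the likelihood cost from O(N^3 D^3) to O(D^3):

    log p(Y) = -ND/2 log 2pi - (N-1)/2 log|Sigma_n| - 1/2 log|N K_h + Sigma_n|
               - 1/2 sum_n y_n' Sigma_n^-1 y_n + N^2/2 ybar' Sigma_n^-1 K_h (N K_h + Sigma_n)^-1 ybar

where Sigma_n is the single-gene covariance, K_h the cluster-layer Gram
matrix on the concatenated grid, and ybar the across-gene mean vector.
Clustering proceeds agglomeratively: starting from singletons, apply
the merge that most increases the summed log marginal likelihood;
when no merge improves, re-optimize the shared hyperparameters and
repeat the agglomeration in an EM fashion.

## Worked example

Simulate three genes with four replicates at 13 two-hour time points,
fit the two-layer model per gene, inspect the variance attribution,
rank by signal-to-replicate+noise ratio, and predict a latent profile:

```python
import numpy as np
import hgptime as h

spec = h.HierarchySpec(
    layers=(("gene", h.KernelParams(6.0, 0.1)), ("replicate", h.KernelParams(3.4, 0.05))),
    noise_variance=0.6,
)
cfg = h.SimConfig(spec=spec, n_genes=3, replicate_grids=tuple([tuple(range(0, 26, 2))] * 4), seed=42)
data = h.simulate(cfg).obs

fits = {}
for k, gene in enumerate(data.group_labels(0)):
    sub = data.select((gene,))
    fits[gene] = h.fit(sub, h.default_spec(sub), restarts=3, seed=k)

for gene, fitted in fits.items():
    frac = h.variance_decomposition(fitted)
    print(f"{gene}: variance split gene/replicate/noise = "
          f"{frac[0]:.0%}/{frac[1]:.0%}/{frac[2]:.0%}")

for gene, score in h.rank_genes(fits):
    print(f"rank {gene}: score {score:.2f}")

post = h.predict(data.select(("g001",)), fits["g001"], "gene", ("g001",), [5.0, 13.0])
print("g001 latent profile at t=5,13h:",
      np.round(post.mean, 2), "+/-", np.round(np.sqrt(post.variance), 2))
```

Output:

```
g001: variance split gene/replicate/noise = 78%/19%/3%
g002: variance split gene/replicate/noise = 71%/27%/2%
g003: variance split gene/replicate/noise = 51%/43%/6%
rank g001: score 3.56
rank g002: score 2.44
rank g003: score 1.03
g001 latent profile at t=5,13h: [ 1.06 -3.61] +/- [0.77 0.77]
```

The variance split reads like a replicate diagnostic: g001's expression
is dominated by the shared profile (78%), while g003's replicates
disagree more (43% replicate variance), so g001 ranks highest. The
prediction is the posterior over the gene's latent profile g_n(t) —
noise and replicate variance are integrated out, not interpolated.

The same surface is scriptable: `hgptime simulate|fit|rank|cluster|impute`
(see `hgptime --help`); outputs are byte-reproducible given a seed.

## Acceptance script

`scripts/acceptance.py` exercises the whole package from scratch:
it simulates a clustered, replicated dataset from the generative model,
recovers the partition with the agglomerative clusterer (reporting the
adjusted Rand index against the planted truth and the biological
homogeneity index against generated annotations), fits and ranks genes
on a second replicated dataset, and runs a systematic-array imputation
holdout comparing the hierarchical GP with plain-GP and
replicate-averaging baselines. Run it from the repository root:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Intermediate tables (data, partition, fitted parameters, RMSE table)
are written next to the output file.
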