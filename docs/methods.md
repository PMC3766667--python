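# Methods

## Model

All layers use the squared-exponential kernel
k(t, t') = alpha * exp(-gamma (t - t')^2), with amplitude alpha in
squared expression units and inverse squared length-scale gamma in
1/hours^2. A hierarchy is an ordered list of layers from the most
shared to the most specific, plus an iid noise variance beta attached
strictly to the diagonal (never block-wise). Marginally, the covariance
between two observations is the sum of the layer kernels along their
shared group-path ancestry:

- two-layer (gene, replicate): k_g within a gene, + k_f within a
  replicate, + beta on the diagonal;
- three-layer with a root shared by all leaves (cluster, gene,
  replicate): k_h everywhere, + k_g within a gene, + k_f within a
  replicate. The layer count may equal the path depth or depth + 1 (a
  root layer over all records); the builder is depth-agnostic.

Observations are a flat list of (group path, time, value) records;
time grids may be irregular and differ between groups. Records are
always processed in one canonical order (path-lexicographic, then time,
then input order) so covariance matrices are bit-reproducible.

The model assumes zero-mean GP priors. Real expression data is not
zero-mean, so `fit` centres each dataset by its grand mean, stores the
mean on the fitted spec, and `predict` adds it back. This is an
interpretation — an explicit constant mean function profiled during
optimization would be the main alternative; centring biases the fitted
top-layer log-amplitude down by roughly 0.14 natural-log units in the
parameter-recovery world below, which we accept for its simplicity.

## Inference and numerics

- Marginal likelihood, gradients: standard Gaussian identities through
  a Cholesky factorization. Analytic gradients with respect to each
  log-hyperparameter use d logp = 1/2 a' dSigma a - 1/2 tr(Sigma^-1 dSigma)
  with a = Sigma^-1 y; per-layer dSigma is the masked layer Gram (for
  log-amplitude) or its -gamma*(t-t')^2-weighted version (for
  log-gamma).
- Jitter: 1e-8 times the sum of the spec's layer amplitudes is added to
  the data-block diagonal before any Cholesky. A failed factorization
  raises an error carrying the smallest eigenvalue.
- Optimization: L-BFGS-B on log-parameters (positivity by
  construction) with analytic gradients. Bounds keep amplitudes in
  [1e-6, 1e3] x data variance, gamma in [1e-4, 1e4] / range^2, and
  noise floored at 1e-6 x data variance (the model is otherwise free to
  explain everything as short-length-scale signal). Restarts draw
  amplitudes/noise log-uniformly from [0.1 v, v] (v = data variance)
  and gamma uniformly from [1, 25] / range^2; the provided spec is
  always one start, so the result never has lower likelihood than the
  initial spec.
- Degenerate inputs: a single observation fits without error (flat
  directions are bounded by the optimizer box); duplicated times are
  handled by jitter everywhere, including in the sampler.

## Efficient cluster likelihood

For N genes sharing one (replicate, time) layout of size D, the shared
profile h is integrated out analytically. We do not use the textbook
form containing K_h^-1: K_h evaluated on the concatenated grid is
*exactly singular* whenever a time point appears in more than one
replicate (the usual array case). Instead, with B = N K_h + Sigma_n:

    log p(Y) = -ND/2 log 2pi - (N-1)/2 log|Sigma_n| - 1/2 log|B|
               - 1/2 sum_n y_n' Sigma_n^-1 y_n
               + N^2/2 ybar' Sigma_n^-1 K_h B^-1 ybar,

and the posterior of h at the grid is N(N K_h B^-1 ybar, K_h B^-1 Sigma_n).
Only Sigma_n and B (both positive definite through beta and jitter) are
factorized; the cost is O(D^3) + O(N D^2). The package-wide jitter of
the *three-layer* spec is attached to Sigma_n's diagonal, never to K_h,
so the efficient and naive paths factor the same implied full matrix;
they agree to better than 1e-8 in log-likelihood on every tested
instance. When genes do not share a layout the dispatcher silently
falls back to the naive O((ND)^3) path and logs the fallback; the
efficient routine itself raises rather than return a wrong number.

Predictions for the cluster profile at arbitrary times and for a
hypothetical new gene go through generic joint-Gaussian conditioning on
the stacked data (a new gene couples to the data through k_h only; its
prior adds k_g, so its variance dominates the cluster profile's).

## Clustering

Greedy agglomeration under the cluster model: starting from singleton
clusters, evaluate every pairwise merge's change in total log marginal
likelihood and apply the best strictly-positive one; ties break to the
lexicographically smallest (min gene of A, min gene of B). Within a
round the total is monotone non-decreasing by construction. When no
merge improves, the shared hyperparameters (one spec for all clusters —
per-cluster specs would overfit small clusters) are re-optimized by
maximizing the summed cluster log marginal likelihoods.

Each EM round then *re-runs the agglomeration from singletons* under
the new hyperparameters, and the best round by total log marginal
likelihood is returned. The alternative — continuing to merge from the
current partition — can never undo merges made under poor initial
hyperparameters; empirically it recovers planted partitions in 3-4/10
worlds versus 8/10 for the restart scheme, whose ceiling matches greedy
merging under the true hyperparameters. Optional outer restarts redraw
the starting hyperparameters and keep the best solution. Merge scores
are cached per (cluster, hyperparameter setting), so one round costs
about n^2/2 + sum-of-round-sizes likelihood evaluations.

Merging is scored purely by marginal-likelihood improvement; no
partition prior (e.g. Dirichlet-process prior odds) is applied.

Validation statistics: BHI (fraction of within-cluster gene pairs
sharing at least one annotation term; undefined and raising on
all-singleton partitions) and the adjusted Rand index (delegated to
scikit-learn; cross-checked in tests against the contingency-table
formula).

## Imputation

Systematic missingness removes whole arrays — every gene's value at one
(replicate, time) coordinate; random missingness removes individual
entries. Methods: the two-layer hierarchical GP (per-gene fit on
training data only, posterior mean of the replicate-level function at
the target); a plain GP that lumps replicates; and replicate mean /
median at exactly duplicated time points (which raise when no retained
replicate shares the target time — averaging cannot extrapolate).
Hyperparameters are refitted after each removal, on the training split
only, to avoid leakage. The harness reports RMSE against the held-out
truth and against the cross-replicate median of the retained values at
the held coordinate, per method and per randomization; failing methods
record NaN rather than aborting the table.

## Synthetic data

The generator draws from the generative model exactly, layer by layer:
the root function of each top-level group on the union of all time
grids, each child as its parent's values at the child's times plus an
independent draw from the child's kernel, and iid noise last. Sampling
order is fixed, so a seed pins the dataset bit-for-bit; truths for
every latent function are recorded for tests. The layered scheme equals
one joint draw in distribution; this is certified empirically by the
moment check below rather than assumed.

Planted clusters split genes evenly in id order. Annotations give each
cluster 3 private terms carried by its genes with probability 0.6, plus
20 background terms at probability 0.05 — fixture constants chosen to
make the BHI discriminative between planted and random partitions.

### Stated worlds and what green tests establish

- Generative moment check: 20,000 replicate pairs at one time point;
  empirical variance and cross-replicate covariance match
  alpha_g + alpha_f + beta and alpha_g within 3 Monte-Carlo standard
  errors. This certifies the sampler against the marginal model.
- Parameter recovery: 50 genes at 13 two-hour time points x 8
  replicates, truth alpha_g=6.0, alpha_f=3.4, beta=0.6 (the 60/34/6
  variance attribution of a strongly replicate-variable gene),
  gamma_g=0.1, gamma_f=0.05. The gammas are package choices (no
  published values exist): a first candidate with rough replicate
  deviations (gamma_f=0.2) was rejected at design time because a
  short-length-scale replicate kernel is statistically confusable with
  iid noise. Four of the five log-hyperparameters recover with MAE
  0.2-0.4. The top-layer log-amplitude disperses with sd ~0.55 for
  *any* true gamma: on a fixed 24 h domain with 13 samples, amplitude
  and length-scale of a squared-exponential GP are only jointly
  estimable along a ridge (only their product-like combination is
  consistently estimable under fixed-domain asymptotics). Its MAE
  ~0.55 therefore reflects an information limit of the design, not an
  estimator defect: the optimizer attains a higher likelihood than the
  truth on every gene.
- Planted-cluster recovery: 30 genes in 5 clusters, amplitudes
  4 / 0.5 / 0.3 with beta=0.2 (cluster amplitude 4x the summed
  gene+replicate+noise), two replicates staggered at
  (0,4,...,20) and (2,6,...,22) hours. Staggering gives the cluster
  profile 12 distinct support points; with only 6 shared times, 5
  random smooth curves collide by chance often enough that even greedy
  merging under the true hyperparameters fails half the time. Adjusted
  Rand >= 0.9 in 8/10 seeds.
- Imputation ordering: 8 genes x 8 replicates x 6 shared times (48
  arrays), 2 arrays removed per randomization, 10 randomizations. The
  hierarchical GP beats the plain GP and both averaging baselines on
  >= 8/10 randomizations (direction only — absolute RMSEs depend on the
  synthetic scale).

None of these worlds emulate microarray technical artifacts
(cross-sectional array effects, probe-level noise, non-Gaussian tails),
so green tests establish correctness of the machinery on model-faithful
data, not performance claims on real arrays.

## Known limitations

- Gaussian noise only; non-Gaussian likelihoods would break conjugacy.
- No sparse/inducing-point approximations: plain-GP costs are cubic in
  the per-gene data size, and the clustering's initial merge scan is
  quadratic in the number of genes.
- One kernel family (squared-exponential); the kernel interface admits
  others but no model selection is provided.
- The mean model is a learned constant per gene; trends that real
  normalization pipelines leave behind are absorbed into the kernels.
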