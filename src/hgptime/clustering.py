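"""Greedy agglomerative clustering of genes under the cluster model.

Starting from singleton clusters, the merge that most increases the
summed log marginal likelihood is applied greedily; when no merge
improves, the shared hyperparameters are re-optimized on the current
partition and merging resumes (an EM-style alternation). Merge scores
use the efficient cluster likelihood whenever the genes share one
measurement layout, falling back to the naive likelihood otherwise.

Validation helpers: the biological homogeneity index (BHI, the fraction
of within-cluster gene pairs sharing at least one annotation term) and
the adjusted Rand index against a reference partition.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from sklearn.metrics import adjusted_rand_score

from .errors import StructureError, UndefinedStatisticError
from .hier_gp import (
    HierarchySpec,
    ObservationSet,
    _fit_bounds,
    _random_start,
    log_marginal_grad,
)
from .cluster_model import ClusterData, cluster_log_marginal

__all__ = ["Partition", "MergeStep", "agglomerate", "bhi", "adjusted_rand"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MergeStep:
    """Record of one accepted greedy merge (for auditing/monotonicity checks)."""

    em_round: int
    clusters_before: tuple[tuple[str, ...], ...]
    pair: tuple[tuple[str, ...], tuple[str, ...]]
    delta: float
    total_after: float
    spec: HierarchySpec


@dataclass(frozen=True)
class Partition:
    """Disjoint clusters of gene ids with per-cluster log marginal likelihoods."""

    clusters: tuple[tuple[str, ...], ...]
    log_marginals: tuple[float, ...]
    spec: HierarchySpec | None = None
    history: tuple[MergeStep, ...] = field(default=(), compare=False, repr=False)

    def __post_init__(self) -> None:
        clusters = tuple(tuple(sorted(str(g) for g in c)) for c in self.clusters)
        if len(clusters) != len(self.log_marginals):
            raise StructureError("one log marginal per cluster required")
        allg = [g for c in clusters for g in c]
        if len(allg) != len(set(allg)):
            raise StructureError("clusters are not disjoint")
        object.__setattr__(self, "clusters", clusters)
        object.__setattr__(self, "log_marginals", tuple(float(x) for x in self.log_marginals))

    @property
    def total_log_marginal(self) -> float:
        return float(sum(self.log_marginals))

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted(g for c in self.clusters for g in c))

    def labels(self) -> dict[str, int]:
        """Gene -> cluster index (clusters ordered by their smallest gene id)."""
        order = sorted(range(len(self.clusters)), key=lambda i: self.clusters[i][0])
        return {g: rank for rank, i in enumerate(order) for g in self.clusters[i]}


# ---------------------------------------------------------------------------
# validation statistics
# ---------------------------------------------------------------------------


def bhi(partition: Partition, annotations: Mapping[str, set]) -> float:
    """Biological homogeneity index of a partition.

    The proportion, over all unordered within-cluster gene pairs, of
    pairs whose annotation sets intersect. Genes absent from the
    annotation table have the empty set. Undefined (raises) when every
    cluster is a singleton.
    """
    hits = 0
    pairs = 0
    for cluster in partition.clusters:
        for a, b in itertools.combinations(cluster, 2):
            pairs += 1
            if set(annotations.get(a, ())) & set(annotations.get(b, ())):
                hits += 1
    if pairs == 0:
        raise UndefinedStatisticError("BHI undefined: partition has no within-cluster pairs")
    return hits / pairs


def adjusted_rand(partition: Partition, reference: Partition) -> float:
    """Adjusted Rand index between two partitions of the same gene set."""
    if partition.genes != reference.genes:
        raise StructureError("partitions cover different gene universes")
    genes = partition.genes
    la = partition.labels()
    lb = reference.labels()
    return float(adjusted_rand_score([lb[g] for g in genes], [la[g] for g in genes]))


# ---------------------------------------------------------------------------
# agglomeration
# ---------------------------------------------------------------------------


def _as_gene_map(genes) -> dict[str, ObservationSet]:
    if isinstance(genes, ObservationSet):
        data = ClusterData.from_observations(genes)
        return dict(zip(data.gene_ids, data.gene_obs))
    if isinstance(genes, ClusterData):
        return dict(zip(genes.gene_ids, genes.gene_obs))
    return {str(g): (o if o.depth == 1 else o.drop_root_level()) for g, o in dict(genes).items()}


class _Scorer:
    """Caches per-cluster log marginals for one hyperparameter setting."""

    def __init__(self, gene_map: dict[str, ObservationSet], spec: HierarchySpec):
        self.gene_map = gene_map
        self.spec = spec
        self._cache: dict[tuple[str, ...], float] = {}

    def data_for(self, cluster: tuple[str, ...]) -> ClusterData:
        return ClusterData(
            gene_ids=cluster, gene_obs=tuple(self.gene_map[g] for g in cluster)
        )

    def lm(self, cluster: tuple[str, ...]) -> float:
        if cluster not in self._cache:
            self._cache[cluster] = cluster_log_marginal(self.data_for(cluster), self.spec)
        return self._cache[cluster]


def _merge_phase(
    scorer: _Scorer,
    clusters: list[tuple[str, ...]],
    em_round: int,
    history: list[MergeStep],
) -> bool:
    """Apply improving merges greedily; return True if any merge happened."""
    merged_any = False
    while len(clusters) > 1:
        # pairs in lexicographic (min gene of A, min gene of B) order; the
        # strict '>' keeps the first maximum, i.e. the smallest tied pair
        ordered = sorted(clusters, key=lambda c: c[0])
        best = None
        best_delta = 0.0
        for i, j in itertools.combinations(range(len(ordered)), 2):
            a, b = ordered[i], ordered[j]
            merged = tuple(sorted(a + b))
            delta = scorer.lm(merged) - scorer.lm(a) - scorer.lm(b)
            if delta > best_delta:
                best_delta = delta
                best = (a, b)
        if best is None:
            break
        a, b = best
        before = tuple(sorted(clusters))
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(tuple(sorted(a + b)))
        merged_any = True
        total = sum(scorer.lm(c) for c in clusters)
        history.append(
            MergeStep(
                em_round=em_round,
                clusters_before=before,
                pair=(a, b),
                delta=best_delta,
                total_after=total,
                spec=scorer.spec,
            )
        )
        logger.info(
            "merge %s + %s (delta=%.4f, total=%.4f)", a, b, best_delta, total
        )
    return merged_any


def _refit_shared_spec(
    scorer: _Scorer, clusters: list[tuple[str, ...]], spec: HierarchySpec
) -> HierarchySpec:
    """Maximize the summed cluster log marginals over the shared log-params."""
    combined = [scorer.data_for(c).combined() for c in clusters]
    all_vals = np.concatenate([o.values for o in combined])
    all_times = np.concatenate([o.times for o in combined])
    yvar = float(np.var(all_vals))
    t_range = float(np.max(all_times) - np.min(all_times))
    bounds = _fit_bounds(spec, yvar, t_range)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def negobj(vec: np.ndarray) -> tuple[float, np.ndarray]:
        s = spec.with_log_params(vec)
        total = 0.0
        grad = np.zeros_like(vec)
        try:
            for o in combined:
                ll, g = log_marginal_grad(o, s)
                total += ll
                grad += g
        except Exception:
            return 1e12, np.zeros_like(vec)
        if not np.isfinite(total):
            return 1e12, np.zeros_like(vec)
        return -total, -grad

    x0 = np.clip(spec.log_params(), lo, hi)
    res = optimize.minimize(negobj, x0, jac=True, method="L-BFGS-B", bounds=bounds)
    if np.isfinite(res.fun) and -res.fun > -negobj(x0)[0]:
        return spec.with_log_params(res.x)
    return spec


def agglomerate(
    genes,
    init_spec: HierarchySpec,
    max_em_iters: int = 5,
    seed: int = 0,
    restarts: int = 1,
    tol: float = 1e-4,
) -> Partition:
    """Greedy agglomerative clustering with EM hyperparameter updates.

    Parameters
    ----------
    genes
        A depth-2 (gene, replicate) :class:`ObservationSet`, a
        :class:`ClusterData`, or a mapping gene id -> depth-1
        ObservationSet. Values are assumed (approximately) zero-mean.
    init_spec
        Three-layer spec (cluster, gene, replicate) used as the first
        restart's starting hyperparameters.
    max_em_iters
        Cap on merge/re-optimize alternations per restart.
    seed, restarts
        Further restarts redraw starting log-hyperparameters from
        data-scaled ranges; the highest-total-likelihood solution wins.
    tol
        An EM round that changes no cluster and improves the total log
        marginal likelihood by <= tol terminates the run.

    Returns the best :class:`Partition`, carrying the final shared spec
    and the full merge history. The total log marginal likelihood is
    non-decreasing over accepted merges and EM rounds.
    """
    if init_spec.n_layers != 3:
        raise StructureError("init_spec must have three layers (cluster, gene, replicate)")
    if max_em_iters < 1:
        raise ValueError("max_em_iters must be >= 1")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    gene_map = _as_gene_map(genes)
    ids = sorted(gene_map)
    rng = np.random.default_rng(seed)
    all_vals = np.concatenate([gene_map[g].values for g in ids])
    all_times = np.concatenate([gene_map[g].times for g in ids])
    yvar = float(np.var(all_vals))
    t_range = float(np.max(all_times) - np.min(all_times))

    start_specs = [init_spec]
    for _ in range(restarts - 1):
        start_specs.append(init_spec.with_log_params(_random_start(rng, init_spec, yvar, t_range)))

    best: Partition | None = None
    for spec in start_specs:
        part = _run_em(gene_map, ids, spec, max_em_iters, tol)
        if best is None or part.total_log_marginal > best.total_log_marginal:
            best = part
    assert best is not None
    return best


def _run_em(
    gene_map: dict[str, ObservationSet],
    ids: list[str],
    spec: HierarchySpec,
    max_em_iters: int,
    tol: float,
) -> Partition:
    """One EM run: each round re-runs the agglomeration from singletons
    under the current hyperparameters (E-like step), then re-optimizes
    the shared hyperparameters on that round's partition (M step). The
    best round by total log marginal likelihood is returned; within a
    round the total is monotone non-decreasing by construction (every
    accepted merge has delta > 0)."""
    history: list[MergeStep] = []
    best: tuple[float, list[tuple[str, ...]], _Scorer] | None = None
    prev_clusters: list[tuple[str, ...]] | None = None
    prev_total = -np.inf
    for em_round in range(max_em_iters):
        scorer = _Scorer(gene_map, spec)
        clusters: list[tuple[str, ...]] = [(g,) for g in ids]
        _merge_phase(scorer, clusters, em_round, history)
        clusters.sort()
        total = sum(scorer.lm(c) for c in clusters)
        if best is None or total > best[0]:
            best = (total, list(clusters), scorer)
        if prev_clusters == clusters and total - prev_total <= tol:
            break
        prev_clusters, prev_total = list(clusters), total
        if em_round < max_em_iters - 1:
            spec = _refit_shared_spec(scorer, clusters, spec)
            if np.allclose(spec.log_params(), scorer.spec.log_params()):
                break  # M step stationary: next round would repeat exactly
    assert best is not None
    total, clusters, scorer = best
    return Partition(
        clusters=tuple(clusters),
        log_marginals=tuple(scorer.lm(c) for c in clusters),
        spec=scorer.spec,
        history=tuple(history),
    )
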