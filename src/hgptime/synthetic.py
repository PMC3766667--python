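"""Sampling from the hierarchical generative model (the test-fixture engine).

Datasets are drawn layer by layer: the root function of each top-level
group is sampled on the union of all time grids; every child function
is its parent's values at the child's times plus an independent draw
from the child layer's kernel; iid Gaussian noise (variance beta) is
added at the bottom. Because parents are drawn on the union grid, every
latent function's true values are available to tests.

With a three-layer spec and ``n_clusters`` set, genes are planted into
clusters (split as evenly as possible, in gene-id order) and a matching
annotation table can be generated: each cluster owns a pool of private
terms assigned to its genes with fixed probability, on top of shared
background terms, making the BHI discriminative between the planted and
random partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import StructureError
from .hier_gp import HierarchySpec, ObservationSet
from .kernels import KernelParams, sq_exp_cov

__all__ = ["AnnotationConfig", "SimConfig", "SimResult", "simulate"]

_SAMPLE_JITTER = 1e-8


@dataclass(frozen=True)
class AnnotationConfig:
    """Annotation model for planted clusters.

    Each cluster gets ``n_private`` private terms; a gene carries each
    private term of its own cluster with probability ``p_private`` and
    each of ``n_background`` background terms with probability
    ``p_background``.
    """

    n_private: int = 3
    p_private: float = 0.6
    n_background: int = 20
    p_background: float = 0.05


@dataclass(frozen=True)
class SimConfig:
    """Stated world of one simulation.

    ``spec`` is the ground-truth hierarchy: two layers (gene,
    replicate) or three (cluster, gene, replicate, requiring
    ``n_clusters``). ``replicate_grids`` lists each replicate's time
    grid in hours (may be irregular and differ between replicates).
    """

    spec: HierarchySpec
    n_genes: int
    replicate_grids: tuple[tuple[float, ...], ...]
    n_clusters: int | None = None
    annotations: AnnotationConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        grids = tuple(tuple(float(t) for t in g) for g in self.replicate_grids)
        if len(grids) == 0 or any(len(g) == 0 for g in grids):
            raise ValueError("replicate_grids must be non-empty")
        if self.spec.n_layers == 3:
            if self.n_clusters is None or not (1 <= self.n_clusters <= self.n_genes):
                raise StructureError("three-layer spec requires 1 <= n_clusters <= n_genes")
        elif self.spec.n_layers == 2:
            if self.n_clusters is not None:
                raise StructureError("planted clusters require a three-layer spec")
        else:
            raise StructureError("simulation supports two- or three-layer specs")
        object.__setattr__(self, "replicate_grids", grids)

    @property
    def gene_names(self) -> tuple[str, ...]:
        width = max(3, len(str(self.n_genes)))
        return tuple(f"g{i:0{width}d}" for i in range(1, self.n_genes + 1))

    @property
    def replicate_names(self) -> tuple[str, ...]:
        return tuple(f"r{i}" for i in range(1, len(self.replicate_grids) + 1))


@dataclass(frozen=True)
class SimResult:
    """Simulated data plus every latent truth.

    ``latents`` maps (level_name, group_path) to (times, true values);
    ``partition`` maps gene -> cluster label (three-layer only);
    ``annotations`` maps gene -> set of term ids (when configured).
    """

    obs: ObservationSet
    latents: dict = field(repr=False)
    partition: dict | None = None
    annotations: dict | None = None
    config: SimConfig | None = field(default=None, repr=False)


def _draw_gp(rng: np.random.Generator, times: np.ndarray, params: KernelParams) -> np.ndarray:
    """One zero-mean draw; jitter keeps duplicated times factorizable."""
    K = sq_exp_cov(times, times, params)
    K[np.diag_indices_from(K)] += _SAMPLE_JITTER * params.amplitude
    L = np.linalg.cholesky(K)
    return L @ rng.standard_normal(times.size)


def planted_partition(config: SimConfig) -> dict[str, str]:
    """Gene -> cluster label, genes split as evenly as possible in order."""
    assert config.n_clusters is not None
    labels = {}
    for i, gene in enumerate(config.gene_names):
        labels[gene] = f"c{(i % config.n_clusters) + 1}"
    return labels


def _draw_annotations(
    rng: np.random.Generator,
    partition: dict[str, str],
    cfg: AnnotationConfig,
) -> dict[str, set]:
    clusters = sorted(set(partition.values()))
    private = {c: [f"{c}_T{j}" for j in range(1, cfg.n_private + 1)] for c in clusters}
    background = [f"BG{j}" for j in range(1, cfg.n_background + 1)]
    anno: dict[str, set] = {}
    for gene in sorted(partition):
        terms = {t for t in private[partition[gene]] if rng.random() < cfg.p_private}
        terms |= {t for t in background if rng.random() < cfg.p_background}
        anno[gene] = terms
    return anno


def simulate(config: SimConfig) -> SimResult:
    """Draw one dataset from the hierarchy; bit-reproducible given the seed.

    Sampling order is fixed (clusters, then genes, then replicates, in
    name order; noise last per replicate) so a seed pins the dataset
    exactly. Latent truths for every level are recorded on the union
    grid (top/middle layers) and the replicate grids (bottom layer).
    """
    rng = np.random.default_rng(config.seed)
    spec = config.spec
    grids = [np.asarray(g, dtype=float) for g in config.replicate_grids]
    union = np.unique(np.concatenate(grids))
    # index of each replicate's times in the union grid
    grid_idx = [np.searchsorted(union, g) for g in grids]

    names = spec.level_names
    latents: dict = {}
    records = []

    if spec.n_layers == 3:
        part = planted_partition(config)
        cluster_names = sorted(set(part.values()))
        h_vals = {}
        for c in cluster_names:
            h_vals[c] = _draw_gp(rng, union, spec.layers[0][1])
            latents[(names[0], (c,))] = (union.copy(), h_vals[c].copy())
        parent_of = {g: h_vals[part[g]] for g in config.gene_names}
        gene_layer, rep_layer = spec.layers[1][1], spec.layers[2][1]
        gene_level, rep_level = names[1], names[2]
        partition = part
    else:
        parent_of = {g: np.zeros(union.size) for g in config.gene_names}
        gene_layer, rep_layer = spec.layers[0][1], spec.layers[1][1]
        gene_level, rep_level = names[0], names[1]
        partition = None

    beta = spec.noise_variance
    for gene in config.gene_names:
        g_vals = parent_of[gene] + _draw_gp(rng, union, gene_layer)
        latents[(gene_level, (gene,))] = (union.copy(), g_vals.copy())
        for rep, grid, idx in zip(config.replicate_names, grids, grid_idx):
            f_vals = g_vals[idx] + _draw_gp(rng, grid, rep_layer)
            latents[(rep_level, (gene, rep))] = (grid.copy(), f_vals.copy())
            y = f_vals + np.sqrt(beta) * rng.standard_normal(grid.size) + spec.mean
            for t, v in zip(grid, y):
                records.append(((gene, rep), float(t), float(v)))

    annotations = None
    if partition is not None and config.annotations is not None:
        annotations = _draw_annotations(rng, partition, config.annotations)

    obs = ObservationSet.from_records(records).canonical()
    return SimResult(
        obs=obs, latents=latents, partition=partition, annotations=annotations, config=config
    )
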