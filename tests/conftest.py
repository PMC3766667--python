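"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's vectorized covariance
assembly: they loop entry-by-entry over records with the block rules
written out explicitly per hierarchy depth, evaluate Gaussian densities
through scipy.stats, and condition joint Gaussians by direct partitioned
solves, so they provide an independent route to every quantity under test.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from hgptime import HierarchySpec, KernelParams, ObservationSet
from hgptime.hier_gp import JITTER_SCALE


def se(t, u, params: KernelParams) -> float:
    return params.amplitude * np.exp(-params.inv_lengthscale * (t - u) ** 2)


# ---------------------------------------------------------------------------
# entry-wise covariance oracles (explicit block rules per depth)
# ---------------------------------------------------------------------------


def oracle_two_layer_cov(obs: ObservationSet, spec: HierarchySpec) -> np.ndarray:
    """Same gene -> k_g (+ k_f same replicate) (+ beta on the diagonal)."""
    kg, kf = spec.layers[0][1], spec.layers[1][1]
    n = len(obs)
    S = np.zeros((n, n))
    for i, (pi, ti, _) in enumerate(obs.records()):
        for j, (pj, tj, _) in enumerate(obs.records()):
            v = 0.0
            if pi[0] == pj[0]:
                v += se(ti, tj, kg)
                if pi[1] == pj[1]:
                    v += se(ti, tj, kf)
            if i == j:
                v += spec.noise_variance
            S[i, j] = v
    return S


def oracle_three_layer_cov(obs: ObservationSet, spec: HierarchySpec) -> np.ndarray:
    """Cluster root shared by all; k_g within gene; k_f within replicate."""
    kh, kg, kf = (p for _, p in spec.layers)
    n = len(obs)
    S = np.zeros((n, n))
    for i, (pi, ti, _) in enumerate(obs.records()):
        for j, (pj, tj, _) in enumerate(obs.records()):
            v = se(ti, tj, kh)
            if pi[0] == pj[0]:
                v += se(ti, tj, kg)
                if pi[1] == pj[1]:
                    v += se(ti, tj, kf)
            if i == j:
                v += spec.noise_variance
            S[i, j] = v
    return S


def oracle_cross_cov(
    obs: ObservationSet,
    spec: HierarchySpec,
    level_name: str,
    group_path: tuple,
    query_times,
) -> np.ndarray:
    """Entry-wise data-latent covariance: sum the layer kernels down to
    the deepest layer at which the record's path agrees with group_path
    (never deeper than the queried level; no noise term)."""
    offset = spec.layer_offset(obs.depth)
    level = spec.level_names.index(level_name)
    q = np.asarray(query_times, dtype=float)
    C = np.zeros((len(obs), q.size))
    for i, (pi, ti, _) in enumerate(obs.records()):
        for ell in range(level + 1):
            need = ell + offset
            if tuple(pi[:need]) == tuple(group_path[:need]):
                for k, tq in enumerate(q):
                    C[i, k] += se(ti, tq, spec.layers[ell][1])
    return C


def oracle_query_prior(spec: HierarchySpec, level_name: str, query_times) -> np.ndarray:
    level = spec.level_names.index(level_name)
    q = np.asarray(query_times, dtype=float)
    K = np.zeros((q.size, q.size))
    for ell in range(level + 1):
        for a, ta in enumerate(q):
            for b, tb in enumerate(q):
                K[a, b] += se(ta, tb, spec.layers[ell][1])
    return K


def oracle_condition(
    data_cov: np.ndarray, cross: np.ndarray, query_prior: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Partitioned-Gaussian conditional via direct solves."""
    sol = np.linalg.solve(data_cov, np.column_stack([y, cross]))
    mean = cross.T @ sol[:, 0]
    cov = query_prior - cross.T @ sol[:, 1:]
    return mean, 0.5 * (cov + cov.T)


def oracle_mvn_logpdf(y: np.ndarray, cov: np.ndarray) -> float:
    return float(stats.multivariate_normal(mean=np.zeros(len(y)), cov=cov, allow_singular=False).logpdf(y))


def jittered(cov: np.ndarray, spec: HierarchySpec) -> np.ndarray:
    out = cov.copy()
    out[np.diag_indices_from(out)] += JITTER_SCALE * spec.total_amplitude
    return out


# ---------------------------------------------------------------------------
# random instance builders
# ---------------------------------------------------------------------------


def random_params(rng: np.random.Generator) -> KernelParams:
    return KernelParams(
        amplitude=float(np.exp(rng.uniform(-1.0, 1.5))),
        inv_lengthscale=float(np.exp(rng.uniform(-3.5, -0.5))),
    )


def random_two_layer_spec(rng: np.random.Generator) -> HierarchySpec:
    return HierarchySpec(
        layers=(("gene", random_params(rng)), ("replicate", random_params(rng))),
        noise_variance=float(np.exp(rng.uniform(-3.0, -0.5))),
    )


def random_three_layer_spec(rng: np.random.Generator) -> HierarchySpec:
    return HierarchySpec(
        layers=(
            ("cluster", random_params(rng)),
            ("gene", random_params(rng)),
            ("replicate", random_params(rng)),
        ),
        noise_variance=float(np.exp(rng.uniform(-3.0, -0.5))),
    )


def random_two_layer_obs(
    rng: np.random.Generator,
    n_genes: int = 2,
    n_reps: int = 2,
    n_times: int = 4,
    irregular: bool = True,
) -> ObservationSet:
    recs = []
    for g in range(n_genes):
        for r in range(n_reps):
            if irregular:
                times = np.sort(rng.uniform(0.0, 12.0, size=rng.integers(2, n_times + 1)))
            else:
                times = np.linspace(0.0, 12.0, n_times)
            for t in times:
                recs.append(((f"g{g}", f"r{r}"), float(t), float(rng.normal())))
    return ObservationSet.from_records(recs)


def random_shared_grid_cluster(
    rng: np.random.Generator, n_genes: int, n_reps: int, n_times: int
):
    """Genes sharing one (replicate, time) layout, as on arrays."""
    from hgptime import ClusterData

    times = np.sort(rng.uniform(0.0, 12.0, size=n_times))
    ids, obs = [], []
    for g in range(n_genes):
        recs = []
        for r in range(n_reps):
            for t in times:
                recs.append(((f"r{r}",), float(t), float(rng.normal())))
        ids.append(f"g{g:02d}")
        obs.append(ObservationSet.from_records(recs))
    return ClusterData(gene_ids=tuple(ids), gene_obs=tuple(obs))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260918)
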