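"""Hierarchical Gaussian process regression for replicated time series.

A hierarchy of GPs models structured expression data: a latent profile at
each level of a grouping tree is drawn from a GP centred on its parent's
profile. Marginally, any two observations are jointly Gaussian with
covariance equal to the *sum of the layer kernels along their shared
ancestry*, plus iid noise variance ``beta`` on the diagonal. For the
canonical two-layer case (gene g, replicate f) the block for replicates
r, r' of one gene is

    K_g + K_f + beta*I   if r == r'
    K_g                  otherwise.

The hierarchy may be arbitrarily deep (e.g. gene -> experiment ->
replicate for data fusion, or cluster -> gene -> replicate for the
cluster model); this module is depth-agnostic.

Observations live in an :class:`ObservationSet` (one record per
measurement: a path of group labels, a time in hours, a value); the
model is an immutable :class:`HierarchySpec` (one kernel per layer plus
the noise variance). Time sampling may be completely irregular and
differ between groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import linalg, optimize

from .errors import NumericalError, StructureError
from .kernels import KernelParams, sq_exp_cov

__all__ = [
    "ObservationSet",
    "HierarchySpec",
    "PosteriorSummary",
    "build_covariance",
    "log_marginal",
    "log_marginal_grad",
    "fit",
    "cross_covariance",
    "predict",
    "variance_decomposition",
    "rank_genes",
    "default_spec",
]

logger = logging.getLogger(__name__)

#: Relative diagonal jitter added before every Cholesky factorization.
JITTER_SCALE = 1e-8


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObservationSet:
    """Flat set of measurements, each tagged with a group path and a time.

    ``paths[i]`` is an ordered tuple of group labels from root to leaf
    (e.g. ``("geneA", "rep1")``); all paths must share one depth. Times
    are decimal hours and may repeat; there is no grid requirement.
    """

    paths: tuple[tuple[str, ...], ...]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        paths = tuple(tuple(str(x) for x in p) for p in self.paths)
        times = np.asarray(self.times, dtype=float).ravel()
        values = np.asarray(self.values, dtype=float).ravel()
        if len(paths) == 0:
            raise StructureError("ObservationSet must contain at least one record")
        if not (len(paths) == times.size == values.size):
            raise StructureError("paths, times and values must have equal length")
        depth = len(paths[0])
        if any(len(p) != depth for p in paths):
            raise StructureError("all group paths must have the same depth")
        if not np.all(np.isfinite(times)):
            raise ValueError("times contain non-finite entries")
        if not np.all(np.isfinite(values)):
            raise ValueError("values contain non-finite entries")
        object.__setattr__(self, "paths", paths)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.paths)

    @property
    def depth(self) -> int:
        return len(self.paths[0])

    @classmethod
    def from_records(cls, records: Iterable[tuple[Sequence[str], float, float]]) -> "ObservationSet":
        recs = list(records)
        return cls(
            paths=tuple(tuple(r[0]) for r in recs),
            times=np.array([r[1] for r in recs], dtype=float),
            values=np.array([r[2] for r in recs], dtype=float),
        )

    def records(self):
        for p, t, v in zip(self.paths, self.times, self.values):
            yield p, float(t), float(v)

    def canonical(self) -> "ObservationSet":
        """Return records in the package-wide canonical order.

        Sort by path lexicographically, then by time, then by input
        order (the sort is stable), so covariance matrices are
        bit-reproducible given the same input.
        """
        order = sorted(range(len(self)), key=lambda i: (self.paths[i], self.times[i]))
        if order == list(range(len(self))):
            return self
        return self.take(order)

    def take(self, indices) -> "ObservationSet":
        idx = list(indices)
        return ObservationSet(
            paths=tuple(self.paths[i] for i in idx),
            times=self.times[idx],
            values=self.values[idx],
        )

    def select(self, prefix: Sequence[str]) -> "ObservationSet":
        """Records whose path starts with ``prefix``."""
        pre = tuple(str(x) for x in prefix)
        idx = [i for i, p in enumerate(self.paths) if p[: len(pre)] == pre]
        if not idx:
            raise StructureError(f"no records with path prefix {pre!r}")
        return self.take(idx)

    def drop_root_level(self) -> "ObservationSet":
        """Remove the leading path component (e.g. strip the gene label)."""
        if self.depth < 2:
            raise StructureError("cannot drop the only path level")
        return ObservationSet(
            paths=tuple(p[1:] for p in self.paths), times=self.times, values=self.values
        )

    def with_root_level(self, label: str) -> "ObservationSet":
        """Prepend a group label to every path."""
        return ObservationSet(
            paths=tuple((str(label),) + p for p in self.paths),
            times=self.times,
            values=self.values,
        )

    def group_labels(self, level: int = 0) -> list[str]:
        """Distinct labels at a path position, in sorted order."""
        return sorted({p[level] for p in self.paths})


@dataclass(frozen=True)
class HierarchySpec:
    """Kernel parameters for each hierarchy layer plus the noise variance.

    ``layers`` runs from the top (most shared) layer to the bottom (most
    specific); ``noise_variance`` (beta) is iid measurement noise added
    to the diagonal only. ``mean`` is a learned constant subtracted from
    the data before likelihood evaluation and re-added to predictions
    (the GP priors themselves are zero-mean).
    """

    layers: tuple[tuple[str, KernelParams], ...]
    noise_variance: float
    mean: float = 0.0

    def __post_init__(self) -> None:
        layers = tuple((str(n), p) for n, p in self.layers)
        if len(layers) == 0:
            raise StructureError("HierarchySpec needs at least one layer")
        names = [n for n, _ in layers]
        if len(set(names)) != len(names):
            raise StructureError(f"duplicate layer names in {names}")
        beta = float(self.noise_variance)
        if not np.isfinite(beta) or beta <= 0.0:
            raise ValueError(f"noise_variance must be positive, got {self.noise_variance!r}")
        mean = float(self.mean)
        if not np.isfinite(mean):
            raise ValueError("mean must be finite")
        object.__setattr__(self, "layers", layers)
        object.__setattr__(self, "noise_variance", beta)
        object.__setattr__(self, "mean", mean)

    @property
    def level_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def total_amplitude(self) -> float:
        return float(sum(p.amplitude for _, p in self.layers))

    def level_index(self, level_name: str) -> int:
        try:
            return self.level_names.index(level_name)
        except ValueError:
            raise StructureError(
                f"unknown level {level_name!r}; levels are {self.level_names}"
            ) from None

    def layer_offset(self, depth: int) -> int:
        """Path-prefix offset: layer ell applies when two paths agree on
        their first ``ell + offset`` components.

        Layer count must equal the path depth, or depth + 1 when a root
        layer shared by all records is included.
        """
        offset = depth + 1 - self.n_layers
        if offset not in (0, 1):
            raise StructureError(
                f"spec with {self.n_layers} layers is incompatible with path depth {depth}"
            )
        return offset

    # -- log-parameter vector [log a_1, log g_1, ..., log a_L, log g_L, log beta]

    def log_params(self) -> np.ndarray:
        vec = []
        for _, p in self.layers:
            if p.inv_lengthscale <= 0.0:
                raise ValueError("inv_lengthscale must be > 0 to use the log parameterization")
            vec.extend([np.log(p.amplitude), np.log(p.inv_lengthscale)])
        vec.append(np.log(self.noise_variance))
        return np.array(vec)

    def with_log_params(self, vec) -> "HierarchySpec":
        vec = np.asarray(vec, dtype=float).ravel()
        if vec.size != 2 * self.n_layers + 1:
            raise ValueError(f"expected {2 * self.n_layers + 1} log-parameters, got {vec.size}")
        exp = np.exp(vec)
        layers = tuple(
            (name, KernelParams(amplitude=exp[2 * i], inv_lengthscale=exp[2 * i + 1]))
            for i, (name, _) in enumerate(self.layers)
        )
        return HierarchySpec(layers=layers, noise_variance=exp[-1], mean=self.mean)

    def to_dict(self) -> dict:
        return {
            "layers": [{"name": n, **p.to_dict()} for n, p in self.layers],
            "noise_variance": self.noise_variance,
            "mean": self.mean,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HierarchySpec":
        layers = tuple(
            (lay["name"], KernelParams(lay["amplitude"], lay["inv_lengthscale"]))
            for lay in d["layers"]
        )
        return cls(layers=layers, noise_variance=d["noise_variance"], mean=d.get("mean", 0.0))


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior mean and covariance of one latent function at query times."""

    query_times: np.ndarray
    mean: np.ndarray
    covariance: np.ndarray
    level_name: str
    group_path: tuple[str, ...]

    def __post_init__(self) -> None:
        q = np.asarray(self.query_times, dtype=float).ravel()
        m = np.asarray(self.mean, dtype=float).ravel()
        c = np.asarray(self.covariance, dtype=float)
        if not (q.size == m.size == c.shape[0] == c.shape[1]):
            raise StructureError("inconsistent posterior dimensions")
        object.__setattr__(self, "query_times", q)
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "covariance", c)
        object.__setattr__(self, "group_path", tuple(str(x) for x in self.group_path))

    @property
    def variance(self) -> np.ndarray:
        return np.diag(self.covariance)


# ---------------------------------------------------------------------------
# covariance assembly
# ---------------------------------------------------------------------------


def _prefix_ids(paths: Sequence[tuple[str, ...]], length: int) -> np.ndarray:
    """Integer id per record of its path prefix of the given length."""
    table: dict[tuple[str, ...], int] = {}
    ids = np.empty(len(paths), dtype=np.int64)
    for i, p in enumerate(paths):
        key = p[:length]
        ids[i] = table.setdefault(key, len(table))
    return ids


def _layer_masks(obs: ObservationSet, spec: HierarchySpec) -> list[np.ndarray | None]:
    """Boolean mask per layer: mask[i, j] iff the layer's kernel couples
    records i and j (paths agree on the layer's required prefix).
    ``None`` stands for the all-ones mask of a root layer."""
    offset = spec.layer_offset(obs.depth)
    masks: list[np.ndarray | None] = []
    for ell in range(spec.n_layers):
        p = ell + offset
        if p == 0:
            masks.append(None)
        else:
            ids = _prefix_ids(obs.paths, p)
            masks.append(ids[:, None] == ids[None, :])
    return masks


def _layer_grams(obs: ObservationSet, spec: HierarchySpec) -> list[np.ndarray]:
    """Masked Gram matrix of each layer on the observation times."""
    masks = _layer_masks(obs, spec)
    t = obs.times
    grams = []
    for (name, params), mask in zip(spec.layers, masks):
        K = sq_exp_cov(t, t, params)
        if mask is not None:
            K = np.where(mask, K, 0.0)
        grams.append(K)
    return grams


def build_covariance(obs: ObservationSet, spec: HierarchySpec, *, jitter: float = 0.0) -> np.ndarray:
    """Marginal covariance of the observations under the hierarchy.

    Entry (i, j) sums k_L(t_i, t_j) over every layer L down to which the
    two records' group paths agree, plus ``noise_variance`` on the
    diagonal. Records are first put in canonical order (path, then time,
    then input order); pass an already-canonical set to control ordering.
    """
    obs = obs.canonical()
    grams = _layer_grams(obs, spec)
    sigma = grams[0].copy()
    for K in grams[1:]:
        sigma += K
    sigma[np.diag_indices_from(sigma)] += spec.noise_variance + jitter
    return sigma


def _default_jitter(spec: HierarchySpec) -> float:
    return JITTER_SCALE * spec.total_amplitude


def _chol(mat: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor; on failure raise with the smallest eigenvalue."""
    try:
        return linalg.cholesky(mat, lower=True)
    except linalg.LinAlgError:
        wmin = float(np.min(linalg.eigvalsh(mat)))
        raise NumericalError(
            f"Cholesky factorization failed; smallest eigenvalue = {wmin:.6e}"
        ) from None


def _chol_logdet(L: np.ndarray) -> float:
    return 2.0 * float(np.sum(np.log(np.diag(L))))


# ---------------------------------------------------------------------------
# marginal likelihood and gradients
# ---------------------------------------------------------------------------


def log_marginal(obs: ObservationSet, spec: HierarchySpec) -> float:
    """Log marginal likelihood of the data under the hierarchy.

    Zero-mean multivariate Gaussian log density (after subtracting
    ``spec.mean``) with covariance :func:`build_covariance`; evaluated
    through a Cholesky factorization with the package-wide jitter.
    """
    obs = obs.canonical()
    sigma = build_covariance(obs, spec, jitter=_default_jitter(spec))
    L = _chol(sigma)
    y = obs.values - spec.mean
    alpha = linalg.cho_solve((L, True), y)
    n = len(obs)
    return float(-0.5 * n * np.log(2.0 * np.pi) - 0.5 * _chol_logdet(L) - 0.5 * y @ alpha)


def log_marginal_grad(obs: ObservationSet, spec: HierarchySpec) -> tuple[float, np.ndarray]:
    """Log marginal likelihood and its gradient w.r.t. the log-parameters.

    The gradient is ordered as ``spec.log_params()``:
    ``[d/dlog a_1, d/dlog g_1, ..., d/dlog beta]``, using
    d logp = 0.5 * a' dSigma a - 0.5 * tr(Sigma^-1 dSigma), a = Sigma^-1 y.
    """
    obs = obs.canonical()
    grams = _layer_grams(obs, spec)
    n = len(obs)
    sigma = grams[0].copy()
    for K in grams[1:]:
        sigma += K
    beta = spec.noise_variance
    sigma[np.diag_indices_from(sigma)] += beta + _default_jitter(spec)
    L = _chol(sigma)
    y = obs.values - spec.mean
    a = linalg.cho_solve((L, True), y)
    ll = -0.5 * n * np.log(2.0 * np.pi) - 0.5 * _chol_logdet(L) - 0.5 * y @ a
    sinv = linalg.cho_solve((L, True), np.eye(n))

    t = obs.times
    d2 = (t[:, None] - t[None, :]) ** 2
    grad = np.empty(2 * spec.n_layers + 1)
    for ell, (name, params) in enumerate(spec.layers):
        K = grams[ell]  # dSigma/dlog(amplitude) -- masked layer Gram itself
        grad[2 * ell] = 0.5 * (a @ K @ a) - 0.5 * float(np.sum(sinv * K))
        dG = -params.inv_lengthscale * d2 * K  # dSigma/dlog(gamma)
        grad[2 * ell + 1] = 0.5 * (a @ dG @ a) - 0.5 * float(np.sum(sinv * dG))
    grad[-1] = 0.5 * beta * (a @ a) - 0.5 * beta * float(np.trace(sinv))
    return float(ll), grad


# ---------------------------------------------------------------------------
# hyperparameter optimization
# ---------------------------------------------------------------------------


def _fit_bounds(spec: HierarchySpec, yvar: float, t_range: float) -> list[tuple[float, float]]:
    v = max(yvar, 1e-12)
    r2 = max(t_range, 1e-6) ** 2
    amp_lo, amp_hi = np.log(1e-6 * v), np.log(1e3 * v)
    gam_lo, gam_hi = np.log(1e-4 / r2), np.log(1e4 / r2)
    bounds = []
    for _ in range(spec.n_layers):
        bounds.append((amp_lo, amp_hi))
        bounds.append((gam_lo, gam_hi))
    bounds.append((np.log(1e-6 * v), np.log(1e2 * v)))  # beta floored at 1e-6 * data variance
    return bounds


def _random_start(rng: np.random.Generator, spec: HierarchySpec, yvar: float, t_range: float) -> np.ndarray:
    """Random initial log-parameters: amplitudes and beta log-uniform on
    [0.1*v, v]; gamma uniform on [1/range^2, 25/range^2]."""
    v = max(yvar, 1e-12)
    r2 = max(t_range, 1e-6) ** 2
    vec = np.empty(2 * spec.n_layers + 1)
    for ell in range(spec.n_layers):
        vec[2 * ell] = rng.uniform(np.log(0.1 * v), np.log(v))
        vec[2 * ell + 1] = np.log(rng.uniform(1.0 / r2, 25.0 / r2))
    vec[-1] = rng.uniform(np.log(0.1 * v), np.log(v))
    return vec


def fit(
    obs: ObservationSet,
    spec: HierarchySpec,
    restarts: int = 3,
    seed: int = 0,
) -> HierarchySpec:
    """Type-II maximum likelihood over the log-hyperparameters.

    The data is centred by its grand mean (stored on the returned spec
    and re-added by :func:`predict`). Optimization is L-BFGS-B with
    analytic gradients; the provided spec is one start and the remaining
    ``restarts - 1`` starts are drawn from data-scaled ranges. The best
    parameters over all starts are returned; the result never has lower
    log marginal likelihood than the initial spec.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    obs = obs.canonical()
    mu = float(np.mean(obs.values))
    centred = ObservationSet(paths=obs.paths, times=obs.times, values=obs.values - mu)
    spec0 = replace(spec, mean=0.0)
    yvar = float(np.var(centred.values))
    t_range = float(np.max(obs.times) - np.min(obs.times))
    bounds = _fit_bounds(spec0, yvar, t_range)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def negobj(vec: np.ndarray) -> tuple[float, np.ndarray]:
        try:
            ll, g = log_marginal_grad(centred, spec0.with_log_params(vec))
        except NumericalError:
            return 1e12, np.zeros_like(vec)
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(vec)
        return -ll, -g

    rng = np.random.default_rng(seed)
    starts = [np.clip(spec0.log_params(), lo, hi)]
    for _ in range(restarts - 1):
        starts.append(np.clip(_random_start(rng, spec0, yvar, t_range), lo, hi))

    best_vec = starts[0]
    best_ll = -negobj(starts[0])[0]
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(negobj, x0, jac=True, method="L-BFGS-B", bounds=bounds)
        any_converged = any_converged or bool(res.success)
        if np.isfinite(res.fun) and -res.fun > best_ll:
            best_ll = -res.fun
            best_vec = res.x
    if not any_converged:
        warnings.warn(
            "hyperparameter optimization did not report convergence on any restart; "
            "returning the best point found",
            RuntimeWarning,
            stacklevel=2,
        )
    return replace(spec0.with_log_params(best_vec), mean=mu)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def cross_covariance(
    obs: ObservationSet,
    spec: HierarchySpec,
    level_name: str,
    group_path: Sequence[str],
    query_times,
) -> np.ndarray:
    """Covariance between the data and one latent function of the hierarchy.

    Entry (i, q) sums k_L(t_i, t_q) over the layers from the top down to
    the deepest layer at which record i's path agrees with
    ``group_path`` (at most the queried level). In the two-layer case
    this is cov(y, g_n) = k_g and cov(y, f_nr') = k_g + k_f if r == r',
    else k_g. The noise variance never appears. ``group_path`` may name
    an unseen group (new-member prediction).
    """
    obs = obs.canonical()
    q = np.asarray(query_times, dtype=float).ravel()
    if not np.all(np.isfinite(q)):
        raise ValueError("query_times contain non-finite entries")
    level = spec.level_index(level_name)
    offset = spec.layer_offset(obs.depth)
    gpath = tuple(str(x) for x in group_path)
    need = level + offset
    if len(gpath) != need:
        raise StructureError(
            f"group_path for level {level_name!r} must have length {need}, got {len(gpath)}"
        )
    C = np.zeros((len(obs), q.size))
    for ell in range(level + 1):
        p = ell + offset
        _, params = spec.layers[ell]
        if p == 0:
            rows = np.ones(len(obs), dtype=bool)
        else:
            rows = np.array([path[:p] == gpath[:p] for path in obs.paths])
        if np.any(rows):
            C[rows] += sq_exp_cov(obs.times[rows], q, params)
    return C


def _query_prior(spec: HierarchySpec, level_name: str, query_times) -> np.ndarray:
    """Prior covariance of the latent at a level: sum of layer kernels
    from the top down to that level (no noise)."""
    q = np.asarray(query_times, dtype=float).ravel()
    level = spec.level_index(level_name)
    K = np.zeros((q.size, q.size))
    for ell in range(level + 1):
        K += sq_exp_cov(q, q, spec.layers[ell][1])
    return K


def predict(
    obs: ObservationSet,
    spec: HierarchySpec,
    level_name: str,
    group_path: Sequence[str],
    query_times,
) -> PosteriorSummary:
    """Posterior of one latent function given the data.

    Standard Gaussian conditioning: mean = C' Sigma^-1 (y - mu) + mu and
    covariance = K_qq - C' Sigma^-1 C, with Sigma the full data
    covariance, C the data-latent cross covariance, and K_qq the
    latent's prior at the query times.
    """
    obs = obs.canonical()
    sigma = build_covariance(obs, spec, jitter=_default_jitter(spec))
    L = _chol(sigma)
    C = cross_covariance(obs, spec, level_name, group_path, query_times)
    Kqq = _query_prior(spec, level_name, query_times)
    y = obs.values - spec.mean
    sinv_C = linalg.cho_solve((L, True), C)
    mean = C.T @ linalg.cho_solve((L, True), y) + spec.mean
    cov = Kqq - C.T @ sinv_C
    cov = 0.5 * (cov + cov.T)
    return PosteriorSummary(
        query_times=np.asarray(query_times, dtype=float).ravel(),
        mean=mean,
        covariance=cov,
        level_name=level_name,
        group_path=tuple(group_path),
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def variance_decomposition(spec: HierarchySpec) -> np.ndarray:
    """Fraction of the marginal variance attributed to each layer and to noise.

    Returns ``(amp_1/T, ..., amp_L/T, beta/T)`` with T the total; the
    fractions sum to one exactly.
    """
    amps = np.array([p.amplitude for _, p in spec.layers] + [spec.noise_variance])
    return amps / amps.sum()


def rank_genes(fitted_specs: Mapping[str, HierarchySpec]) -> list[tuple[str, float]]:
    """Rank genes by signal-to-(replicate + noise) variance ratio.

    For two-layer fits the score is ``amp_top / (amp_bottom + beta)``;
    genes are sorted by descending score, ties broken by gene id.
    """
    scored = []
    for gene, spec in fitted_specs.items():
        if spec.n_layers != 2:
            raise StructureError(
                f"rank_genes requires two-layer specs; gene {gene!r} has {spec.n_layers}"
            )
        a_g = spec.layers[0][1].amplitude
        a_f = spec.layers[1][1].amplitude
        scored.append((str(gene), a_g / (a_f + spec.noise_variance)))
    return sorted(scored, key=lambda kv: (-kv[1], kv[0]))


def default_spec(
    obs: ObservationSet,
    level_names: Sequence[str] = ("gene", "replicate"),
) -> HierarchySpec:
    """Data-scaled starting spec: variance split evenly-ish across layers
    and noise, length-scales spanning a few features of the time range."""
    v = max(float(np.var(obs.values)), 1e-8)
    r2 = max(float(np.max(obs.times) - np.min(obs.times)), 1e-3) ** 2
    n = len(level_names)
    layers = []
    for i, name in enumerate(level_names):
        amp = v * (0.5 if i == 0 else 0.3 / max(n - 1, 1))
        gamma = (4.0 * 2.0**i) / r2
        layers.append((name, KernelParams(amplitude=amp, inv_lengthscale=gamma)))
    return HierarchySpec(layers=tuple(layers), noise_variance=0.2 * v)
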