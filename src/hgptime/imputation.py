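"""Missing-data imputation and holdout evaluation harness.

Two missingness designs are supported: *systematic* (whole arrays, i.e.
all genes at one replicate-time coordinate, removed at once -- the case
replicate-averaging and most imputation methods cannot handle well) and
*random* (individual gene/replicate/time entries removed).

Imputation methods:

- ``hgp``: two-layer hierarchical GP fitted per gene on the training
  data only, posterior mean of the replicate-level function f_nr at the
  missing coordinate (plus the stored gene mean).
- ``gp``: plain GP per gene that lumps all replicates together
  (replicate structure ignored).
- ``mean`` / ``median``: the statistic of the retained replicates of
  the same gene at the exact target time (only applicable when time
  points are duplicated between replicates).

The harness reports RMSE against the held-out truth and against the
cross-replicate median at the held-out coordinate, per method, with a
repeated-randomization wrapper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import BaselineInapplicableError, NoInformationError, StructureError
from .hier_gp import (
    HierarchySpec,
    ObservationSet,
    default_spec,
    fit,
    predict,
)

__all__ = [
    "HoldoutMask",
    "systematic_mask",
    "random_mask",
    "apply_mask",
    "impute_hgp",
    "impute_gp",
    "impute_baseline",
    "run_holdout",
    "repeat_holdout",
    "summarize_repeats",
]

logger = logging.getLogger(__name__)

Target = tuple[str, str, float]  # (gene, replicate, time)


@dataclass(frozen=True)
class HoldoutMask:
    """Held-out coordinates of one randomization.

    ``mode`` is ``"systematic-array"`` (removed lists (replicate, time)
    pairs applying to every gene) or ``"random-entry"`` (removed lists
    (gene, replicate, time) triples).
    """

    mode: str
    removed: tuple[tuple, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("systematic-array", "random-entry"):
            raise ValueError(f"unknown mask mode {self.mode!r}")
        object.__setattr__(self, "removed", tuple(tuple(r) for r in self.removed))


def _check_two_level(obs: ObservationSet) -> None:
    if obs.depth != 2:
        raise StructureError("imputation expects depth-2 (gene, replicate) paths")


def systematic_mask(obs: ObservationSet, n_remove: int, seed: int) -> HoldoutMask:
    """Remove ``n_remove`` whole arrays: distinct (replicate, time) coordinates."""
    _check_two_level(obs)
    arrays = sorted({(p[1], float(t)) for p, t, _ in obs.records()})
    if not (1 <= n_remove < len(arrays)):
        raise ValueError(f"n_remove must be in [1, {len(arrays) - 1}], got {n_remove}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(arrays), size=n_remove, replace=False)
    return HoldoutMask(
        mode="systematic-array", removed=tuple(arrays[i] for i in sorted(idx)), seed=seed
    )


def random_mask(obs: ObservationSet, n_remove: int, seed: int) -> HoldoutMask:
    """Remove ``n_remove`` individual (gene, replicate, time) entries."""
    _check_two_level(obs)
    entries = sorted({(p[0], p[1], float(t)) for p, t, _ in obs.records()})
    if not (1 <= n_remove < len(entries)):
        raise ValueError(f"n_remove must be in [1, {len(entries) - 1}], got {n_remove}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(entries), size=n_remove, replace=False)
    return HoldoutMask(
        mode="random-entry", removed=tuple(entries[i] for i in sorted(idx)), seed=seed
    )


def apply_mask(obs: ObservationSet, mask: HoldoutMask) -> tuple[ObservationSet, ObservationSet]:
    """Split into (train, held) observation sets; held must be non-empty."""
    _check_two_level(obs)
    removed = set(mask.removed)
    if mask.mode == "systematic-array":
        held_idx = [
            i for i, (p, t, _) in enumerate(obs.records()) if (p[1], t) in removed
        ]
    else:
        held_idx = [
            i for i, (p, t, _) in enumerate(obs.records()) if (p[0], p[1], t) in removed
        ]
    if not held_idx:
        raise ValueError("mask removes no existing records")
    if len(held_idx) == len(obs):
        raise ValueError("mask removes every record")
    held_set = set(held_idx)
    train_idx = [i for i in range(len(obs)) if i not in held_set]
    return obs.take(train_idx), obs.take(held_idx)


# ---------------------------------------------------------------------------
# imputation methods
# ---------------------------------------------------------------------------


def _fit_per_gene(
    train: ObservationSet,
    genes: Sequence[str],
    template: HierarchySpec | None,
    level_names: tuple[str, ...],
    restarts: int,
    seed: int,
    collapse: bool,
) -> dict[str, tuple[ObservationSet, HierarchySpec]]:
    fits = {}
    for k, gene in enumerate(sorted(set(genes))):
        sub = train.select((gene,))
        if collapse:
            # plain GP: forget the replicate labels, keep the gene label
            sub = ObservationSet(
                paths=tuple((p[0],) for p in sub.paths), times=sub.times, values=sub.values
            )
        spec0 = template if template is not None else default_spec(sub, level_names)
        fits[gene] = (sub, fit(sub, spec0, restarts=restarts, seed=seed + k))
    return fits


def _posterior_at_targets(
    fits: dict[str, tuple[ObservationSet, HierarchySpec]],
    targets: Sequence[Target],
    level: str,
    path_of: Callable[[Target], tuple[str, ...]],
) -> tuple[np.ndarray, np.ndarray]:
    means = np.empty(len(targets))
    variances = np.empty(len(targets))
    for i, tgt in enumerate(targets):
        gene = tgt[0]
        sub, spec = fits[gene]
        post = predict(sub, spec, level, path_of(tgt), [tgt[2]])
        means[i] = post.mean[0]
        variances[i] = post.variance[0]
    return means, variances


def impute_hgp(
    train: ObservationSet,
    targets: Sequence[Target],
    spec: HierarchySpec | None = None,
    restarts: int = 2,
    seed: int = 0,
    allow_prior: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Hierarchical-GP posterior-mean imputation at the target coordinates.

    A two-layer (gene, replicate) model is fitted per gene on the
    training data; each target value is the posterior mean (and
    variance) of the replicate-level function at the target time, with
    the gene's stored mean re-added. A gene entirely absent from the
    training data raises unless ``allow_prior`` is set, in which case
    the prior (training grand) mean is returned with prior variance.
    """
    _check_two_level(train)
    targets = [(str(g), str(r), float(t)) for g, r, t in targets]
    train_genes = set(train.group_labels(0))
    missing = sorted({g for g, _, _ in targets} - train_genes)
    if missing and not allow_prior:
        raise NoInformationError(f"genes absent from training data: {missing}")
    present = [tgt for tgt in targets if tgt[0] in train_genes]
    fits = _fit_per_gene(
        train,
        [g for g, _, _ in present],
        spec,
        ("gene", "replicate"),
        restarts,
        seed,
        collapse=False,
    )
    means = np.empty(len(targets))
    variances = np.empty(len(targets))
    if present:
        level = next(iter(fits.values()))[1].level_names[-1]
        m, v = _posterior_at_targets(
            fits, present, level, lambda tgt: (tgt[0], tgt[1])
        )
        j = 0
        for i, tgt in enumerate(targets):
            if tgt[0] in train_genes:
                means[i], variances[i] = m[j], v[j]
                j += 1
    grand = float(np.mean(train.values))
    grand_var = float(np.var(train.values))
    for i, tgt in enumerate(targets):
        if tgt[0] not in train_genes:
            means[i], variances[i] = grand, grand_var
    return means, variances


def impute_gp(
    train: ObservationSet,
    targets: Sequence[Target],
    spec: HierarchySpec | None = None,
    restarts: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Plain-GP baseline: one GP per gene over the lumped replicates."""
    _check_two_level(train)
    targets = [(str(g), str(r), float(t)) for g, r, t in targets]
    train_genes = set(train.group_labels(0))
    missing = sorted({g for g, _, _ in targets} - train_genes)
    if missing:
        raise NoInformationError(f"genes absent from training data: {missing}")
    fits = _fit_per_gene(
        train, [g for g, _, _ in targets], spec, ("gene",), restarts, seed, collapse=True
    )
    level = next(iter(fits.values()))[1].level_names[0]
    return _posterior_at_targets(fits, targets, level, lambda tgt: (tgt[0],))


def impute_baseline(
    train: ObservationSet,
    targets: Sequence[Target],
    statistic: str = "mean",
) -> np.ndarray:
    """Replicate-averaging baseline at exactly duplicated time points.

    Per target, the mean or median of the same gene's retained values
    at the identical time across the other replicates. Raises when no
    retained replicate shares the target time.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    _check_two_level(train)
    agg = np.mean if statistic == "mean" else np.median
    by_coord: dict[tuple[str, float], list[float]] = {}
    for p, t, v in train.records():
        by_coord.setdefault((p[0], t), []).append(v)
    out = np.empty(len(targets))
    for i, (g, r, t) in enumerate(targets):
        vals = by_coord.get((str(g), float(t)))
        if not vals:
            raise BaselineInapplicableError(
                f"no retained replicate of gene {g!r} measured at time {t}; "
                "averaging baselines need duplicated time points"
            )
        out[i] = agg(vals)
    return out


# ---------------------------------------------------------------------------
# holdout harness
# ---------------------------------------------------------------------------


def _rmse(pred: np.ndarray, truth: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(pred) - np.asarray(truth)) ** 2)))


def _replicate_median_reference(train: ObservationSet, targets: Sequence[Target]) -> np.ndarray:
    """Cross-replicate median of retained values at each held coordinate (NaN if none)."""
    by_coord: dict[tuple[str, float], list[float]] = {}
    for p, t, v in train.records():
        by_coord.setdefault((p[0], t), []).append(v)
    ref = np.full(len(targets), np.nan)
    for i, (g, r, t) in enumerate(targets):
        vals = by_coord.get((str(g), float(t)))
        if vals:
            ref[i] = np.median(vals)
    return ref


_METHODS: dict[str, Callable] = {
    "hgp": lambda train, targets, seed: impute_hgp(train, targets, seed=seed)[0],
    "gp": lambda train, targets, seed: impute_gp(train, targets, seed=seed)[0],
    "mean": lambda train, targets, seed: impute_baseline(train, targets, "mean"),
    "median": lambda train, targets, seed: impute_baseline(train, targets, "median"),
}


def run_holdout(
    data: ObservationSet,
    mask: HoldoutMask,
    methods: Sequence[str | tuple[str, Callable]] = ("hgp", "gp", "mean", "median"),
    seed: int = 0,
) -> pd.DataFrame:
    """Impute one holdout with each method and score RMSEs.

    Methods are built-in names or ``(name, callable)`` pairs with
    signature ``f(train, targets, seed) -> predictions``. Each method is
    refitted on the training split only. Returns one row per method
    with ``rmse_truth`` (against held-out values) and
    ``rmse_replicate_median`` (against the retained cross-replicate
    median; NaN where never computable). A failing method records NaNs
    instead of aborting the run.
    """
    if not methods:
        raise ValueError("methods must be non-empty")
    train, held = apply_mask(data, mask)
    targets: list[Target] = [(p[0], p[1], t) for p, t, _ in held.records()]
    truth = held.values
    med_ref = _replicate_median_reference(train, targets)
    have_ref = np.isfinite(med_ref)
    rows = []
    for m in methods:
        name, func = (m, _METHODS[m]) if isinstance(m, str) else m
        try:
            pred = np.asarray(func(train, targets, seed), dtype=float)
            rmse_truth = _rmse(pred, truth)
            rmse_med = _rmse(pred[have_ref], med_ref[have_ref]) if have_ref.any() else np.nan
        except Exception as exc:  # record, never abort the table
            logger.warning("method %s failed on this holdout: %s", name, exc)
            rmse_truth = np.nan
            rmse_med = np.nan
        rows.append({"method": name, "rmse_truth": rmse_truth, "rmse_replicate_median": rmse_med})
    return pd.DataFrame(rows)


def repeat_holdout(
    data: ObservationSet,
    mode: str,
    n_remove: int,
    repeats: int,
    methods: Sequence[str | tuple[str, Callable]] = ("hgp", "gp", "mean", "median"),
    seed: int = 0,
) -> pd.DataFrame:
    """Repeat a holdout design over fresh randomizations.

    Returns rows (method, repeat, rmse_truth, rmse_replicate_median);
    summarize with :func:`summarize_repeats`.
    """
    make = systematic_mask if mode.startswith("systematic") else random_mask
    frames = []
    for rep in range(repeats):
        mask = make(data, n_remove, seed + rep)
        tab = run_holdout(data, mask, methods, seed=seed + 1000 * (rep + 1))
        tab.insert(1, "repeat", rep)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def summarize_repeats(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and 2-SD spread of each RMSE column per method over repeats."""
    out = []
    for method, grp in table.groupby("method", sort=False):
        row = {"method": method}
        for col in ("rmse_truth", "rmse_replicate_median"):
            vals = grp[col].to_numpy(dtype=float)
            row[f"{col}_mean"] = float(np.nanmean(vals))
            row[f"{col}_2sd"] = float(2.0 * np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0
        out.append(row)
    return pd.DataFrame(out)
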