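"""Readers and writers for the package's plain-text interchange formats.

The canonical interchange is a long-format table (TSV or CSV, sniffed
by extension) with header ``gene, <level columns...>, time, value``:
one row per measurement, times in decimal hours, missing values encoded
by absent rows (NaN placeholders are rejected). Long format is used
because replicates may have unequal, irregular time grids; a wide
genes-by-arrays convenience reader is provided for the shared-grid case.

Fitted hyperparameters serialize to JSON (one object per gene: layers,
noise variance, stored data mean), partitions and annotation tables to
two-column TSVs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .hier_gp import HierarchySpec, ObservationSet

__all__ = [
    "read_long_table",
    "write_long_table",
    "read_wide_table",
    "write_params_json",
    "read_params_json",
    "write_partition",
    "read_partition",
    "read_annotations",
    "write_annotations",
    "write_predictions",
]


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_long_table(path, level_columns: Sequence[str] = ("replicate",)) -> ObservationSet:
    """Read a long-format expression table into an ObservationSet.

    Requires header columns ``gene``, every name in ``level_columns``,
    ``time`` and ``value``. Duplicate (path, time) rows are retained as
    distinct observations. Rows with non-numeric or missing time/value
    raise a row-addressed error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    required = ["gene", *level_columns, "time", "value"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col in ("time", "value"):
        parsed = np.empty(len(df))
        for i, raw in enumerate(df[col].tolist()):
            try:
                parsed[i] = float(raw)  # correctly-rounded conversion
            except (TypeError, ValueError):
                parsed[i] = np.nan
        bad = np.nonzero(~np.isfinite(parsed))[0]
        if bad.size > 0:
            raise SchemaError(
                f"{path}: non-numeric or missing {col!r} at data row {int(bad[0]) + 1} "
                "(missing values must be encoded by absent rows)"
            )
        df[col] = parsed
    paths = tuple(
        tuple(row) for row in df[["gene", *level_columns]].astype(str).itertuples(index=False)
    )
    return ObservationSet(paths=paths, times=df["time"].to_numpy(), values=df["value"].to_numpy())


def write_long_table(
    obs: ObservationSet, path, level_columns: Sequence[str] = ("replicate",)
) -> None:
    """Write an ObservationSet as a long-format table (canonical row order)."""
    obs = obs.canonical()
    if obs.depth != 1 + len(level_columns):
        raise SchemaError(
            f"paths have depth {obs.depth} but {1 + len(level_columns)} columns were named"
        )
    # shortest-repr strings round-trip float64 exactly through the reader
    df = pd.DataFrame(
        [
            {"gene": p[0], **dict(zip(level_columns, p[1:])), "time": repr(t), "value": repr(v)}
            for p, t, v in obs.records()
        ]
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_wide_table(path, array_metadata) -> ObservationSet:
    """Convenience reader for shared-grid data: genes x arrays matrix.

    ``path`` holds a table with a ``gene`` column and one column per
    array id; ``array_metadata`` a table with columns ``array``,
    ``replicate``, ``time`` mapping each array column to its coordinate.
    """
    path = Path(path)
    mat = pd.read_csv(path, sep=_sep_for(path))
    if "gene" not in mat.columns:
        raise SchemaError(f"{path}: missing required column 'gene'")
    meta = pd.read_csv(Path(array_metadata), sep=_sep_for(array_metadata), dtype=str)
    for col in ("array", "replicate", "time"):
        if col not in meta.columns:
            raise SchemaError(f"{array_metadata}: missing required column {col!r}")
    coords = {
        row.array: (row.replicate, float(row.time)) for row in meta.itertuples(index=False)
    }
    records = []
    for _, row in mat.iterrows():
        gene = str(row["gene"])
        for arr, (rep, t) in coords.items():
            if arr not in mat.columns:
                raise SchemaError(f"{path}: array column {arr!r} named in metadata is absent")
            v = row[arr]
            if pd.isna(v):
                continue  # wide format may legitimately have holes
            records.append(((gene, rep), t, float(v)))
    return ObservationSet.from_records(records).canonical()


def write_params_json(fits: Mapping[str, HierarchySpec], path) -> None:
    """Serialize per-gene fitted specs: {gene: {layers, noise_variance, mean}}."""
    payload = {str(g): spec.to_dict() for g, spec in sorted(fits.items())}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_params_json(path) -> dict[str, HierarchySpec]:
    payload = json.loads(Path(path).read_text())
    return {g: HierarchySpec.from_dict(d) for g, d in payload.items()}


def write_partition(partition, path) -> None:
    """Write gene -> cluster_id rows (cluster ids ordered by smallest gene)."""
    labels = partition.labels()
    df = pd.DataFrame(
        [{"gene": g, "cluster_id": labels[g]} for g in sorted(labels)]
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_partition(path) -> dict[str, str]:
    df = pd.read_csv(Path(path), sep=_sep_for(path), dtype=str)
    for col in ("gene", "cluster_id"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return dict(zip(df["gene"], df["cluster_id"]))


def read_annotations(path) -> dict[str, set]:
    """Read a gene/term table (one pair per row) into gene -> term set."""
    df = pd.read_csv(Path(path), sep=_sep_for(path), dtype=str)
    for col in ("gene", "term"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    anno: dict[str, set] = {}
    for row in df.itertuples(index=False):
        anno.setdefault(str(row.gene), set()).add(str(row.term))
    return anno


def write_annotations(annotations: Mapping[str, set], path) -> None:
    rows = [
        {"gene": g, "term": t}
        for g in sorted(annotations)
        for t in sorted(annotations[g])
    ]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(path, sep=_sep_for(path), index=False)


def write_predictions(posteriors, path, gene_column: str = "gene") -> None:
    """Write PosteriorSummary objects as rows (gene, level, group_path, time, mean, variance)."""
    rows = []
    for post in posteriors:
        gpath = "/".join(post.group_path)
        for t, m, v in zip(post.query_times, post.mean, post.variance):
            rows.append(
                {
                    gene_column: post.group_path[0] if post.group_path else "",
                    "level": post.level_name,
                    "group_path": gpath,
                    "time": t,
                    "mean": m,
                    "variance": v,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")
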