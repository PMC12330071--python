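"""Data containers and I/O for single-cell proteomics quantification matrices.

The central container is :class:`ScpDataset`: a features×cells intensity
matrix with explicit missing values (NaN), a feature-annotation table
(peptide sequence, protein id, PSM-level QC columns), a cell-annotation
table (cell type, MS acquisition run, label channel, numeric covariates),
and an ordered processing history.

Zero intensities are treated as missing on ingestion: a zero reported by a
search engine means the peptide was not quantified in that cell, not that
its abundance is zero.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScpDataset",
    "ProcessingRecord",
    "SchemaError",
    "read_long_table",
    "read_matrix",
    "write_matrix",
    "write_results",
]


class SchemaError(ValueError):
    """Raised when an input table does not satisfy the expected schema."""


@dataclass(frozen=True)
class ProcessingRecord:
    """One entry of a dataset's processing log."""

    step: str
    parameters: Mapping[str, Any]
    features_before: int
    features_after: int
    cells_before: int
    cells_after: int


@dataclass
class ScpDataset:
    """A features×cells intensity matrix with annotations and history.

    Parameters
    ----------
    intensities
        Float DataFrame, rows = feature ids, columns = cell ids. NaN marks
        a missing (unobserved) value; zeros never coexist with
        ``log_transformed=True``.
    feature_annotations
        DataFrame indexed by feature id. Typical columns: ``peptide``,
        ``protein``, and PSM-level QC columns.
    cell_annotations
        DataFrame indexed by cell id with arbitrary descriptors.
    level
        One of ``{"psm", "precursor", "peptide"}``.
    """

    intensities: pd.DataFrame
    feature_annotations: pd.DataFrame
    cell_annotations: pd.DataFrame
    level: str = "psm"
    log_transformed: bool = False
    history: list[ProcessingRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = self.intensities.astype(float)
        if not self.intensities.index.equals(self.feature_annotations.index):
            raise SchemaError(
                "intensity rows and feature annotations are not aligned"
            )
        if not self.intensities.columns.equals(self.cell_annotations.index):
            raise SchemaError(
                "intensity columns and cell annotations are not aligned"
            )
        if self.intensities.index.has_duplicates:
            dup = self.intensities.index[self.intensities.index.duplicated()]
            raise SchemaError(f"duplicated feature ids: {sorted(set(dup))}")
        if self.intensities.columns.has_duplicates:
            dup = self.intensities.columns[self.intensities.columns.duplicated()]
            raise SchemaError(f"duplicated cell ids: {sorted(set(dup))}")
        if self.level not in ("psm", "precursor", "peptide"):
            raise ValueError(f"unknown level {self.level!r}")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_cells(self) -> int:
        return self.intensities.shape[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def observed_mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where an intensity is observed."""
        return self.intensities.notna()

    def record(self, step: str, parameters: Mapping[str, Any],
               before: "ScpDataset") -> None:
        """Append a processing record describing the step that produced self."""
        self.history.append(
            ProcessingRecord(
                step=step,
                parameters=dict(parameters),
                features_before=before.n_features,
                features_after=self.n_features,
                cells_before=before.n_cells,
                cells_after=self.n_cells,
            )
        )

    def copy(self) -> "ScpDataset":
        return ScpDataset(
            intensities=self.intensities.copy(),
            feature_annotations=self.feature_annotations.copy(),
            cell_annotations=self.cell_annotations.copy(),
            level=self.level,
            log_transformed=self.log_transformed,
            history=list(self.history),
        )


# -- readers ---------------------------------------------------------------

#: semantic roles understood by :func:`read_long_table`
MANDATORY_ROLES = ("feature", "cell", "intensity")


def _read_delimited(path: str | os.PathLike) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def read_long_table(
    path: str | os.PathLike,
    column_map: Mapping[str, str],
    level: str = "psm",
) -> ScpDataset:
    """Read a long-format PSM/precursor quantification table.

    ``column_map`` maps semantic roles to column names. Mandatory roles are
    ``feature``, ``cell`` and ``intensity``; any other role (``peptide``,
    ``protein``, ``decoy``, ``contaminant``, ``sample_to_carrier``,
    ``spectral_purity``, ``identification_fdr``, ...) is carried into the
    feature annotations. Duplicate (feature, cell) pairs are collapsed by
    median; zero intensities are stored as missing.
    """
    try:
        table = _read_delimited(path)
    except pd.errors.EmptyDataError:
        table = pd.DataFrame()
    if table.empty and table.shape[1] == 0:
        empty = pd.DataFrame(dtype=float)
        return ScpDataset(
            intensities=empty,
            feature_annotations=pd.DataFrame(index=empty.index),
            cell_annotations=pd.DataFrame(index=empty.columns),
            level=level,
        )
    for role in MANDATORY_ROLES:
        if role not in column_map:
            raise SchemaError(f"column_map lacks the mandatory role {role!r}")
        if column_map[role] not in table.columns:
            raise SchemaError(
                f"column {column_map[role]!r} (role {role!r}) absent from {path}"
            )
    fcol, ccol, icol = (column_map[r] for r in MANDATORY_ROLES)
    raw = pd.to_numeric(table[icol], errors="coerce")
    bad = raw.isna() & table[icol].notna()
    if bad.any():
        raise SchemaError(
            f"non-numeric intensity at row(s) {list(table.index[bad])[:5]}"
        )
    values = raw.mask(raw == 0)  # zeros are missed measurements

    long = pd.DataFrame(
        {"feature": table[fcol], "cell": table[ccol], "intensity": values}
    )
    wide = (
        long.pivot_table(index="feature", columns="cell", values="intensity",
                         aggfunc="median")
        .reindex(index=pd.unique(long["feature"]),
                 columns=pd.unique(long["cell"]))
    )
    wide.index.name = None
    wide.columns.name = None

    annot_roles = [r for r in column_map if r not in MANDATORY_ROLES]
    if annot_roles:
        fa = (
            table[[fcol] + [column_map[r] for r in annot_roles]]
            .drop_duplicates(subset=fcol)
            .set_index(fcol)
        )
        fa.columns = annot_roles
        fa = fa.reindex(wide.index)
        fa.index.name = None
    else:
        fa = pd.DataFrame(index=wide.index)
    ca = pd.DataFrame(index=wide.columns)
    return ScpDataset(intensities=wide, feature_annotations=fa,
                      cell_annotations=ca, level=level)


def read_matrix(
    path: str | os.PathLike,
    feature_annotation_path: str | os.PathLike,
    cell_annotation_path: str | os.PathLike,
    level: str = "peptide",
    log_transformed: bool = False,
) -> ScpDataset:
    """Read a wide features×cells matrix plus its two annotation tables.

    The matrix header row holds cell ids and the first column feature ids;
    annotation tables are keyed by their first column. Ids must match
    exactly (same sets); offenders are reported.
    """
    mat = _read_delimited(path).set_index(
        _read_delimited(path).columns[0]
    )
    mat.index.name = None
    fa = _read_delimited(feature_annotation_path)
    fa = fa.set_index(fa.columns[0])
    fa.index.name = None
    ca = _read_delimited(cell_annotation_path)
    ca = ca.set_index(ca.columns[0])
    ca.index.name = None

    missing_f = mat.index.difference(fa.index)
    extra_f = fa.index.difference(mat.index)
    if len(missing_f) or len(extra_f):
        raise SchemaError(
            f"feature ids unmatched: missing annotation for {list(missing_f)}, "
            f"annotation without matrix row for {list(extra_f)}"
        )
    missing_c = mat.columns.difference(ca.index)
    extra_c = ca.index.difference(mat.columns)
    if len(missing_c) or len(extra_c):
        raise SchemaError(
            f"cell ids unmatched: missing annotation for {list(missing_c)}, "
            f"annotation without matrix column for {list(extra_c)}"
        )
    return ScpDataset(
        intensities=mat.astype(float),
        feature_annotations=fa.loc[mat.index],
        cell_annotations=ca.loc[mat.columns],
        level=level,
        log_transformed=log_transformed,
    )


# -- writers ---------------------------------------------------------------

def write_matrix(ds: ScpDataset, directory: str | os.PathLike,
                 prefix: str = "dataset") -> dict[str, str]:
    """Write a dataset as three TSVs: matrix + feature/cell annotations."""
    os.makedirs(directory, exist_ok=True)
    paths = {
        "matrix": os.path.join(directory, f"{prefix}_matrix.tsv"),
        "features": os.path.join(directory, f"{prefix}_features.tsv"),
        "cells": os.path.join(directory, f"{prefix}_cells.tsv"),
    }
    ds.intensities.to_csv(paths["matrix"], sep="\t", index_label="feature")
    ds.feature_annotations.to_csv(paths["features"], sep="\t",
                                  index_label="feature")
    ds.cell_annotations.to_csv(paths["cells"], sep="\t", index_label="cell")
    return paths


def write_results(
    tables: Mapping[str, pd.DataFrame],
    directory: str | os.PathLike,
) -> dict[str, str]:
    """Write named result tables as TSV, one file per table.

    Column order is the DataFrame's own (deterministic); the index is
    written when it is named or non-trivial.
    """
    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}
    for name, table in tables.items():
        p = os.path.join(directory, f"{name}.tsv")
        write_index = table.index.name is not None or not isinstance(
            table.index, pd.RangeIndex
        )
        table.to_csv(p, sep="\t", index=write_index)
        paths[name] = p
    return paths
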