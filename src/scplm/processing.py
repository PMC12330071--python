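"""Minimal processing workflow: feature QC, cell QC, aggregation, log transform.

The workflow deliberately stops here — no imputation, no normalization, no
batch correction. Those needs are addressed downstream by the linear model
(normalization as a covariate, batch effects as technical variables,
missing values by per-peptide design subsetting).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core_data import ScpDataset

__all__ = [
    "FeatureQcRules",
    "CellQcRules",
    "filter_features",
    "compute_cell_median_cv",
    "filter_cells",
    "aggregate_to_peptides",
    "log_transform",
]


@dataclass(frozen=True)
class FeatureQcRules:
    """PSM/precursor-level quality-control rules; None disables a rule.

    Thresholds are fractions in [0, 1]: a feature is dropped when its
    identification FDR exceeds ``max_identification_fdr``, its
    sample-to-carrier ratio falls below ``min_sample_to_carrier_ratio``,
    or its spectral purity falls below ``min_spectral_purity``.
    """

    drop_decoys: bool = False
    drop_contaminants: bool = False
    max_identification_fdr: Optional[float] = None
    min_sample_to_carrier_ratio: Optional[float] = None
    min_spectral_purity: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("max_identification_fdr", "min_sample_to_carrier_ratio",
                     "min_spectral_purity"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class CellQcRules:
    """Cell-level quality-control rules; None disables a rule.

    ``median_log_intensity_range`` is an open interval in log2 units;
    ``max_median_cv`` bounds the median within-protein coefficient of
    variation (e.g. 0.6 reproduces the common 60 % cut-off).
    """

    min_peptides_per_cell: Optional[int] = None
    median_log_intensity_range: Optional[tuple[float, float]] = None
    max_median_cv: Optional[float] = None
    min_peptides_per_protein_for_cv: int = 3

    def __post_init__(self) -> None:
        if self.median_log_intensity_range is not None:
            lo, hi = self.median_log_intensity_range
            if not lo < hi:
                raise ValueError("median_log_intensity_range must satisfy low < high")
        if self.max_median_cv is not None and self.max_median_cv <= 0:
            raise ValueError("max_median_cv must be positive")


def _require_column(ds: ScpDataset, column: str, rule: str) -> pd.Series:
    if column not in ds.feature_annotations.columns:
        raise KeyError(
            f"rule {rule!r} is active but feature annotation column "
            f"{column!r} is absent"
        )
    return ds.feature_annotations[column]


def filter_features(ds: ScpDataset, rules: FeatureQcRules) -> ScpDataset:
    """Drop features failing any active QC rule and log the step."""
    keep = pd.Series(True, index=ds.feature_ids)
    if rules.drop_decoys:
        keep &= ~_require_column(ds, "decoy", "drop_decoys").astype(bool)
    if rules.drop_contaminants:
        keep &= ~_require_column(ds, "contaminant", "drop_contaminants").astype(bool)
    if rules.max_identification_fdr is not None:
        fdr = _require_column(ds, "identification_fdr", "max_identification_fdr")
        keep &= fdr <= rules.max_identification_fdr
    if rules.min_sample_to_carrier_ratio is not None:
        scr = _require_column(ds, "sample_to_carrier",
                              "min_sample_to_carrier_ratio")
        keep &= scr >= rules.min_sample_to_carrier_ratio
    if rules.min_spectral_purity is not None:
        purity = _require_column(ds, "spectral_purity", "min_spectral_purity")
        keep &= purity >= rules.min_spectral_purity

    out = ScpDataset(
        intensities=ds.intensities.loc[keep],
        feature_annotations=ds.feature_annotations.loc[keep],
        cell_annotations=ds.cell_annotations,
        level=ds.level,
        log_transformed=ds.log_transformed,
        history=list(ds.history),
    )
    out.record("filter_features", rules.__dict__, ds)
    return out


def compute_cell_median_cv(
    ds: ScpDataset,
    min_peptides_per_protein: int = 3,
    protein_column: str = "protein",
) -> pd.Series:
    """Median within-protein coefficient of variation per cell.

    Each peptide's intensities are first divided by that peptide's mean
    across cells (relative intensities). For each protein with at least
    ``min_peptides_per_protein`` peptides observed in a cell, the CV is the
    sample standard deviation over the mean of those relative intensities;
    the cell's value is the median protein CV, NaN when no protein
    qualifies. Requires raw (non-log) intensities.
    """
    if ds.log_transformed:
        raise ValueError("median CV is defined on raw intensities, "
                         "dataset is already log-transformed")
    proteins = ds.feature_annotations[protein_column]
    rel = ds.intensities.div(ds.intensities.mean(axis=1, skipna=True), axis=0)

    out = pd.Series(np.nan, index=ds.cell_ids, dtype=float)
    grouped = {p: sub for p, sub in rel.groupby(proteins)}
    for cell in ds.cell_ids:
        cvs = []
        for sub in grouped.values():
            vals = sub[cell].dropna()
            if len(vals) >= min_peptides_per_protein:
                m = vals.mean()
                if m != 0:
                    cvs.append(vals.std(ddof=1) / m)
        if cvs:
            out[cell] = float(np.median(cvs))
    return out


def filter_cells(ds: ScpDataset, rules: CellQcRules) -> ScpDataset:
    """Drop cells failing any active QC rule and log the step.

    The median log intensity is computed on a provisional log2 of the
    observed raw values (the dataset itself is not mutated); on an already
    log-transformed dataset the stored values are used as-is.
    """
    keep = pd.Series(True, index=ds.cell_ids)
    if rules.min_peptides_per_cell is not None:
        n_obs = ds.observed_mask.sum(axis=0)
        keep &= n_obs >= rules.min_peptides_per_cell
    if rules.median_log_intensity_range is not None:
        lo, hi = rules.median_log_intensity_range
        logged = ds.intensities if ds.log_transformed else np.log2(ds.intensities)
        med = logged.median(axis=0, skipna=True)
        keep &= (med > lo) & (med < hi)
    if rules.max_median_cv is not None:
        cv = compute_cell_median_cv(
            ds, min_peptides_per_protein=rules.min_peptides_per_protein_for_cv
        )
        keep &= ~(cv > rules.max_median_cv)  # NaN CV cells are retained

    out = ScpDataset(
        intensities=ds.intensities.loc[:, keep],
        feature_annotations=ds.feature_annotations,
        cell_annotations=ds.cell_annotations.loc[keep],
        level=ds.level,
        log_transformed=ds.log_transformed,
        history=list(ds.history),
    )
    out.record("filter_cells", rules.__dict__, ds)
    return out


def aggregate_to_peptides(
    ds: ScpDataset,
    key: str = "peptide",
    protein_column: str = "protein",
    ambiguity: str = "error",
) -> ScpDataset:
    """Aggregate PSM/precursor rows to peptides; (peptide, cell) = median.

    A peptide observed in a cell has at least one observed child there.
    Peptides whose children map to more than one protein are handled per
    ``ambiguity``: ``"error"`` (default), ``"drop"``, or
    ``"keep-first-alphabetical"``.
    """
    if ds.level not in ("psm", "precursor"):
        raise ValueError(f"cannot aggregate a dataset at level {ds.level!r}")
    if key not in ds.feature_annotations.columns:
        raise KeyError(f"aggregation key column {key!r} absent")
    peptides = ds.feature_annotations[key]

    proteins = None
    if protein_column in ds.feature_annotations.columns:
        per_pep = ds.feature_annotations.groupby(peptides)[protein_column].agg(
            lambda s: sorted(set(s))
        )
        ambiguous = per_pep[per_pep.str.len() > 1]
        if len(ambiguous):
            if ambiguity == "error":
                raise ValueError(
                    "peptides mapping to multiple proteins: "
                    f"{dict(ambiguous.head(10))}"
                )
            if ambiguity == "drop":
                per_pep = per_pep.drop(ambiguous.index)
            elif ambiguity != "keep-first-alphabetical":
                raise ValueError(f"unknown ambiguity policy {ambiguity!r}")
        proteins = per_pep.str[0]

    agg = ds.intensities.groupby(peptides).median()
    agg = agg.reindex(pd.unique(peptides.dropna()))
    if proteins is not None:
        agg = agg.loc[agg.index.intersection(proteins.index)]
        fa = pd.DataFrame({protein_column: proteins.reindex(agg.index)})
    else:
        fa = pd.DataFrame(index=agg.index)
    agg.index.name = None
    fa.index.name = None

    out = ScpDataset(
        intensities=agg,
        feature_annotations=fa,
        cell_annotations=ds.cell_annotations,
        level="peptide",
        log_transformed=ds.log_transformed,
        history=list(ds.history),
    )
    out.record("aggregate_to_peptides", {"key": key, "ambiguity": ambiguity}, ds)
    return out


def log_transform(ds: ScpDataset, base: float = 2.0) -> ScpDataset:
    """Element-wise log transform of the observed intensities (default log2)."""
    if ds.log_transformed:
        raise ValueError("dataset is already log-transformed")
    values = ds.intensities
    nonpos = (values <= 0)
    if nonpos.any().any():
        rows, cols = np.nonzero(nonpos.to_numpy())
        offenders = [
            (values.index[r], values.columns[c]) for r, c in zip(rows[:5], cols[:5])
        ]
        raise ValueError(f"non-positive observed intensities at {offenders}")
    out = ScpDataset(
        intensities=np.log(values) / np.log(base),
        feature_annotations=ds.feature_annotations,
        cell_annotations=ds.cell_annotations,
        level=ds.level,
        log_transformed=True,
        history=list(ds.history),
    )
    out.record("log_transform", {"base": base}, ds)
    return out
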