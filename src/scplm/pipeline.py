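"""End-to-end pipeline: process → model → variance/differential/components/benchmark.

One flat configuration drives the whole analysis; every stage appends to
the dataset's processing history and the run manifest records every
parameter, so a manifest suffices to re-execute the identical analysis.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Any, Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .components import apca, protein_loadings
from .core_data import ScpDataset, read_long_table, read_matrix, write_results
from .differential import adjust_pvalues, build_contrast, combine_to_protein, \
    test_contrasts
from .evaluation import benchmark
from .modeling import ModelSpec, Variable, batch_corrected, fit_model
from .processing import CellQcRules, FeatureQcRules, aggregate_to_peptides, \
    filter_cells, filter_features, log_transform
from .synthetic import SimulationConfig, simulate
from .variance import global_variance, protein_variance, variance_analysis

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_VARIABLE_ROLES"]

#: conventional roles/kinds for common descriptor names
DEFAULT_VARIABLE_ROLES: dict[str, tuple[str, str]] = {
    "median_intensity": ("normalization", "numeric"),
    "run": ("technical", "categorical"),
    "label": ("technical", "categorical"),
    "celltype": ("biological", "categorical"),
}


def parse_variables(
    formula: str,
    roles: Optional[Mapping[str, str]] = None,
    kinds: Optional[Mapping[str, str]] = None,
) -> tuple[Variable, ...]:
    """Turn ``"median_intensity + run + label + celltype"`` into Variables."""
    roles = dict(roles or {})
    kinds = dict(kinds or {})
    out = []
    for name in (v.strip() for v in formula.split("+")):
        if not name:
            continue
        default_role, default_kind = DEFAULT_VARIABLE_ROLES.get(
            name, ("technical", "categorical")
        )
        out.append(
            Variable(
                name=name,
                role=roles.get(name, default_role),
                kind=kinds.get(name, default_kind),
            )
        )
    return tuple(out)


@dataclass
class RunConfig:
    """Flat configuration of a full analysis run."""

    output_dir: str
    # input: either a simulation, a wide matrix, or a long table
    simulate: Optional[dict] = None
    matrix: Optional[str] = None
    feature_annotations: Optional[str] = None
    cell_annotations: Optional[str] = None
    long_table: Optional[str] = None
    column_map: Optional[dict] = None
    input_level: str = "peptide"
    input_log_transformed: bool = False
    # processing
    feature_qc: Optional[dict] = None
    cell_qc: Optional[dict] = None
    aggregate_key: Optional[str] = None
    log_base: float = 2.0
    # model
    formula: str = "median_intensity + run + label + celltype"
    roles: dict = field(default_factory=dict)
    kinds: dict = field(default_factory=dict)
    ridge_lambda: float = 1e-3
    np_threshold: float = 1.0
    # inference
    contrasts: Sequence[str] = ()       # e.g. ["celltype:typeA-typeB"]
    adjust_method: str = "bh"
    protein_method: str = "simes"
    protein_column: str = "protein"
    # components
    component_variables: Sequence[str] = ()
    n_components: int = 20
    # benchmark
    benchmark_keep: Sequence[str] = ()  # variables kept in batch correction
    bio_label: Optional[str] = None
    tech_label: Optional[str] = None
    kmeans_k: int = 3
    seed: int = 0

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        return cls(**d)


def _load_dataset(config: RunConfig) -> ScpDataset:
    if config.simulate is not None:
        sim = SimulationConfig(**{**config.simulate, "seed": config.seed})
        ds, _ = simulate(sim)
        return ds
    if config.long_table is not None:
        if not config.column_map:
            raise ValueError("long_table input requires a column_map")
        return read_long_table(config.long_table, config.column_map,
                               level=config.input_level)
    if config.matrix is not None:
        return read_matrix(
            config.matrix, config.feature_annotations, config.cell_annotations,
            level=config.input_level,
            log_transformed=config.input_log_transformed,
        )
    raise ValueError("no input configured: set simulate, matrix or long_table")


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the configured analysis; returns the written file paths."""
    os.makedirs(config.output_dir, exist_ok=True)
    ds = _load_dataset(config)

    if config.feature_qc:
        ds = filter_features(ds, FeatureQcRules(**config.feature_qc))
    if config.cell_qc:
        rules = dict(config.cell_qc)
        if rules.get("median_log_intensity_range") is not None:
            rules["median_log_intensity_range"] = tuple(
                rules["median_log_intensity_range"]
            )
        ds = filter_cells(ds, CellQcRules(**rules))
    if config.aggregate_key:
        ds = aggregate_to_peptides(ds, key=config.aggregate_key)
    if not ds.log_transformed:
        ds = log_transform(ds, base=config.log_base)

    spec = ModelSpec(
        variables=parse_variables(config.formula, config.roles, config.kinds),
        ridge_lambda=config.ridge_lambda,
    )
    result = fit_model(ds, spec, np_threshold=config.np_threshold)

    tables: dict[str, pd.DataFrame] = {}
    tables["coefficients"] = pd.DataFrame(
        {
            fid: pd.Series(fit.coefficients,
                           index=[result.design.parameter_names[k]
                                  for k in fit.retained])
            for fid, fit in result.fits.items()
        }
    ).T
    tables["skipped"] = pd.DataFrame(
        sorted(result.skipped.items()), columns=["feature", "reason"]
    )

    vt = variance_analysis(result)
    tables["variance_peptide"] = vt
    tables["variance_global"] = global_variance(vt).rename("percent").reset_index()
    protein_map = None
    if config.protein_column in result.feature_annotations.columns:
        protein_map = result.feature_annotations[config.protein_column]
        tables["variance_protein"] = protein_variance(vt, protein_map)

    for spec_str in config.contrasts:
        variable, _, groups = spec_str.partition(":")
        group_a, _, group_b = groups.partition("-")
        contrast = build_contrast(result.design, variable, group_a, group_b)
        inf = adjust_pvalues(
            test_contrasts(result, contrast),
            method=config.adjust_method, seed=config.seed,
        )
        tables[f"peptide_tests_{variable}_{group_a}_vs_{group_b}"] = inf
        if protein_map is not None:
            tables[f"protein_tests_{variable}_{group_a}_vs_{group_b}"] = (
                combine_to_protein(inf, protein_map,
                                   method=config.protein_method)
            )

    for variable in config.component_variables:
        cr = apca(result, variable, k=config.n_components,
                  dataset=ds.intensities if variable == "unmodelled" else None)
        tables[f"scores_{variable}"] = cr.scores
        tables[f"loadings_{variable}"] = cr.loadings
        tables[f"eigenvalues_{variable}"] = pd.DataFrame(
            {"eigenvalue": cr.eigenvalues,
             "percent_variance": cr.percent_variance}
        )
        if protein_map is not None:
            tables[f"protein_loadings_{variable}"] = protein_loadings(
                cr, protein_map
            )

    if config.bio_label and config.tech_label:
        corrected = batch_corrected(result, keep=list(config.benchmark_keep))
        report = benchmark(
            corrected,
            result.cell_annotations[config.bio_label],
            result.cell_annotations[config.tech_label],
            n_pcs=config.n_components,
            k=config.kmeans_k,
            seed=config.seed,
        )
        tables["benchmark"] = report.metrics.rename_axis("metric").reset_index()
        tables["batch_corrected"] = corrected

    paths = write_results(tables, config.output_dir)

    manifest = {
        "package": "scplm",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "processing_history": [
            {
                "step": rec.step,
                "parameters": {k: repr(v) for k, v in rec.parameters.items()},
                "features": [rec.features_before, rec.features_after],
                "cells": [rec.cells_before, rec.cells_after],
            }
            for rec in ds.history
        ],
        "n_fitted": len(result.fits),
        "n_skipped": len(result.skipped),
        "outputs": paths,
    }
    manifest_path = os.path.join(config.output_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    paths["manifest"] = manifest_path
    return paths
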