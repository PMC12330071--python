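"""Analysis of variance over the fitted per-peptide models.

For each peptide the regression sum of squares of every model variable f,
SSR^(f) = ‖X_{O_j,K_f} β̂_{K_f}‖², and the error sum of squares
SSE = ‖ε̂‖² are converted to percentages,

    %var^(f) = 100 · SSR^(f) / (SSE + Σ_l SSR^(l)),

which sum to 100 per peptide. Global and per-protein summaries are
unweighted means of these percentages across peptides. The intercept is a
baseline, not a variance source, and never appears as a component.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .modeling import ModelResult

__all__ = ["variance_analysis", "global_variance", "protein_variance"]

RESIDUAL = "residual"


def variance_analysis(result: ModelResult) -> pd.DataFrame:
    """Per-peptide variance decomposition.

    Returns a long DataFrame with columns ``feature``, ``component``
    (model variables plus ``"residual"``), ``ss`` (sum of squares, squared
    log-intensity units) and ``percent_variance``. Variables entirely
    dropped for a peptide get SSR = 0, keeping the table rectangular.
    """
    variables = result.variables
    design = result.design
    rows = []
    for fid, fit in result.fits.items():
        ss = {}
        for f in variables:
            k_f = design.variable_columns[f]
            cols_mask = np.isin(fit.retained, k_f)
            if cols_mask.any():
                contrib = (
                    design.matrix[np.ix_(fit.observed, fit.retained[cols_mask])]
                    @ fit.coefficients[cols_mask]
                )
                ss[f] = float(contrib @ contrib)
            else:
                ss[f] = 0.0
        ss[RESIDUAL] = fit.sse
        total = sum(ss.values())
        for comp, value in ss.items():
            rows.append(
                {
                    "feature": fid,
                    "component": comp,
                    "ss": value,
                    "percent_variance": 100.0 * value / total if total > 0 else
                    (100.0 if comp == RESIDUAL else 0.0),
                }
            )
    return pd.DataFrame(rows, columns=["feature", "component", "ss",
                                       "percent_variance"])


def global_variance(variance_table: pd.DataFrame) -> pd.Series:
    """Mean percent variance per component across all peptides."""
    if variance_table.empty:
        raise ValueError("empty variance table")
    return variance_table.groupby("component", sort=False)["percent_variance"].mean()


def protein_variance(
    variance_table: pd.DataFrame, peptide_to_protein: pd.Series
) -> pd.DataFrame:
    """Average the peptide percentages over each protein's peptide set."""
    peptides = variance_table["feature"].unique()
    unmapped = [p for p in peptides if p not in peptide_to_protein.index]
    if unmapped:
        raise KeyError(f"peptides without protein mapping: {unmapped[:10]}")
    tagged = variance_table.assign(
        protein=variance_table["feature"].map(peptide_to_protein)
    )
    out = (
        tagged.groupby(["protein", "component"], sort=False)["percent_variance"]
        .mean()
        .reset_index()
    )
    return out
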