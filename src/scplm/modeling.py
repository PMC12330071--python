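"""Per-peptide adaptive ridge linear modeling of log peptide intensities.

Each peptide j is modeled on the cells where it is observed (O_j) only,
with the design matrix restricted to the parameters that remain
non-constant on those cells (S_j) — missing values are never imputed, the
model adapts instead. Coefficients are estimated by ridge-penalized least
squares with a small penalty (λ = 1e-3 by default) that stabilizes
estimation when the number of observations per parameter (n/p) is close
to 1.

Categorical descriptors are encoded with sum-to-zero contrasts, numeric
descriptors are centered, and an intercept (the peptide's baseline log2
intensity) is always included. Effect matrices per variable and
batch-corrected reconstructions (intercept + retained effects + residuals)
are derived from the fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .core_data import ScpDataset

__all__ = [
    "Variable",
    "ModelSpec",
    "DesignMatrix",
    "PeptideFit",
    "ModelResult",
    "build_design",
    "subset_model",
    "fit_peptide",
    "fit_model",
    "effect_matrix",
    "batch_corrected",
    "median_intensity",
]

#: variance below this is treated as a constant column after subsetting
_CONSTANT_TOL = 1e-12

DEFAULT_LAMBDA = 1e-3

Role = Literal["normalization", "technical", "biological"]
Kind = Literal["categorical", "numeric"]


@dataclass(frozen=True)
class Variable:
    name: str
    role: Role = "technical"
    kind: Kind = "categorical"


@dataclass(frozen=True)
class ModelSpec:
    """Ordered model variables plus the ridge penalty λ."""

    variables: tuple[Variable, ...]
    ridge_lambda: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        if self.ridge_lambda < 0:
            raise ValueError("ridge penalty must be non-negative")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in model spec")


@dataclass
class DesignMatrix:
    """Encoded cells×parameters model matrix.

    Column 0 is the all-ones intercept. ``variable_columns`` maps each
    model variable to its parameter-column index set K_f; ``level_order``
    records the lexicographic level order used by the sum-contrast
    encoding and ``centering`` the mean subtracted from each numeric
    variable.
    """

    matrix: np.ndarray
    parameter_names: list[str]
    variable_columns: dict[str, np.ndarray]
    cell_ids: pd.Index
    level_order: dict[str, list] = field(default_factory=dict)
    centering: dict[str, float] = field(default_factory=dict)

    intercept_index: int = 0

    @property
    def n_parameters(self) -> int:
        return self.matrix.shape[1]

    def encoding_row(self, variable: str, level) -> np.ndarray:
        """Sum-contrast encoding of one level of a categorical variable,
        restricted to that variable's K_f columns."""
        levels = self.level_order[variable]
        if level not in levels:
            raise KeyError(f"unknown level {level!r} of variable {variable!r}")
        a = len(levels)
        row = np.zeros(a - 1)
        i = levels.index(level)
        if i < a - 1:
            row[i] = 1.0
        else:
            row[:] = -1.0
        return row


def build_design(cell_annotations: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Encode cell descriptors into a model matrix.

    Sum-to-zero contrasts for categoricals (a levels → a−1 columns,
    lexicographic order, last level encoded −1 everywhere), global-mean
    centering for numerics, intercept imposed as column 0.
    """
    n = len(cell_annotations)
    columns: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    var_cols: dict[str, np.ndarray] = {}
    level_order: dict[str, list] = {}
    centering: dict[str, float] = {}

    for var in spec.variables:
        if var.name not in cell_annotations.columns:
            raise KeyError(f"variable {var.name!r} not in cell annotations")
        values = cell_annotations[var.name]
        start = len(names)
        if var.kind == "categorical":
            levels = sorted(values.astype(object).unique(), key=str)
            if len(levels) < 2:
                raise ValueError(
                    f"categorical variable {var.name!r} has a single level"
                )
            level_order[var.name] = levels
            codes = values.map({lev: i for i, lev in enumerate(levels)}).to_numpy()
            a = len(levels)
            enc = np.zeros((n, a - 1))
            for i in range(a - 1):
                enc[codes == i, i] = 1.0
            enc[codes == a - 1, :] = -1.0
            for i in range(a - 1):
                columns.append(enc[:, i])
                names.append(f"{var.name}[{levels[i]}]")
        else:
            x = values.astype(float).to_numpy()
            if not np.all(np.isfinite(x)):
                raise ValueError(f"numeric variable {var.name!r} has non-finite values")
            mu = float(x.mean())
            centering[var.name] = mu
            columns.append(x - mu)
            names.append(var.name)
        var_cols[var.name] = np.arange(start, len(names))

    return DesignMatrix(
        matrix=np.column_stack(columns),
        parameter_names=names,
        variable_columns=var_cols,
        cell_ids=cell_annotations.index,
        level_order=level_order,
        centering=centering,
    )


def subset_model(design: DesignMatrix, observed: np.ndarray) -> np.ndarray:
    """Retained-parameter index set S_j for an observed-cell index set O_j.

    S_j keeps every column whose variance over the observed cells exceeds
    a small tolerance, plus the intercept (which is constant by
    definition but always estimable). Columns that become linearly
    dependent on earlier retained columns after subsetting are dropped as
    well: a missing categorical level under sum coding leaves no
    constant column but makes the subsetted design rank-deficient, and a
    penalized exact fit would then smear the (large) intercept across
    the aliased parameters. Earlier columns win, so the intercept and
    the first variables of the model formula take precedence.
    """
    sub = design.matrix[observed]
    var = sub.var(axis=0)
    candidates = np.flatnonzero(var > _CONSTANT_TOL)
    if design.intercept_index not in candidates:
        candidates = np.concatenate(([design.intercept_index], candidates))
    candidates = np.sort(candidates)

    # greedy order-preserving rank filter on the subsetted columns
    retained: list[int] = []
    basis: Optional[np.ndarray] = None  # orthonormal basis of kept columns
    for k in candidates:
        col = sub[:, k]
        if basis is None:
            norm = np.linalg.norm(col)
            if norm > 0:
                basis = (col / norm)[:, None]
                retained.append(k)
            continue
        resid = col - basis @ (basis.T @ col)
        if np.linalg.norm(resid) ** 2 > 1e-10 * max(col @ col, 1.0):
            basis = np.column_stack([basis, resid / np.linalg.norm(resid)])
            retained.append(k)
    return np.asarray(retained, dtype=int)


@dataclass
class PeptideFit:
    """A fitted per-peptide model on its observed cells and retained parameters."""

    feature_id: str
    observed: np.ndarray      # O_j: integer cell indices
    retained: np.ndarray      # S_j: integer parameter indices
    coefficients: np.ndarray  # β̂ aligned with `retained`
    residuals: np.ndarray     # ε̂ aligned with `observed`
    sse: float
    sigma2: float
    df_residual: int          # ν = |O_j| − |S_j|
    n_over_p: float


@dataclass
class ModelResult:
    """Design matrix, per-peptide fits, and skip records for one dataset."""

    design: DesignMatrix
    spec: ModelSpec
    fits: dict[str, PeptideFit]
    skipped: dict[str, str]
    feature_annotations: pd.DataFrame
    cell_annotations: pd.DataFrame

    @property
    def feature_ids(self) -> list[str]:
        return list(self.fits)

    @property
    def cell_ids(self) -> pd.Index:
        return self.design.cell_ids

    @property
    def variables(self) -> list[str]:
        return [v.name for v in self.spec.variables]

    def design_for(self, fit: PeptideFit) -> np.ndarray:
        """X restricted to the fit's observed cells and retained parameters."""
        return self.design.matrix[np.ix_(fit.observed, fit.retained)]


def fit_peptide(
    y: np.ndarray,
    x_sub: np.ndarray,
    ridge_lambda: float = DEFAULT_LAMBDA,
    feature_id: str = "",
    observed: Optional[np.ndarray] = None,
    retained: Optional[np.ndarray] = None,
) -> PeptideFit:
    """Ridge-penalized least squares on one peptide's observed intensities.

    Solves β̂ = (XᵀX + λI)⁻¹ Xᵀy, with residuals ε̂ = y − Xβ̂,
    SSE = ‖ε̂‖², ν = |O_j| − |S_j| and σ̂² = SSE/ν.
    """
    n, p = x_sub.shape
    xtx = x_sub.T @ x_sub
    xty = x_sub.T @ y
    try:
        beta = linalg.solve(xtx + ridge_lambda * np.eye(p), xty,
                            assume_a="pos")
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"singular system for {feature_id!r}") from err
    if not np.all(np.isfinite(beta)):
        raise np.linalg.LinAlgError(f"non-finite solution for {feature_id!r}")
    residuals = y - x_sub @ beta
    sse = float(residuals @ residuals)
    nu = n - p
    return PeptideFit(
        feature_id=feature_id,
        observed=observed if observed is not None else np.arange(n),
        retained=retained if retained is not None else np.arange(p),
        coefficients=beta,
        residuals=residuals,
        sse=sse,
        sigma2=sse / nu if nu > 0 else np.nan,
        df_residual=nu,
        n_over_p=n / p,
    )


def median_intensity(ds: ScpDataset) -> pd.Series:
    """Per-cell median of the observed log2 intensities (normalization factor)."""
    values = ds.intensities if ds.log_transformed else np.log2(ds.intensities)
    return values.median(axis=0, skipna=True)


def fit_model(
    ds: ScpDataset,
    spec: ModelSpec,
    np_threshold: float = 1.0,
) -> ModelResult:
    """Fit the adaptive ridge model to every peptide of a log dataset.

    Peptides are skipped when n/p = |O_j|/|S_j| falls below
    ``np_threshold``, and always when n/p <= 1 (the model would be
    saturated or under-determined). A variable named ``median_intensity``
    that is absent from the cell annotations is computed on demand from
    the data as the per-cell median log2 intensity.
    """
    if not ds.log_transformed:
        raise ValueError("fit_model expects log-transformed intensities")
    annotations = ds.cell_annotations.copy()
    for var in spec.variables:
        if var.name == "median_intensity" and var.name not in annotations.columns:
            annotations[var.name] = median_intensity(ds)

    design = build_design(annotations, spec)
    X = design.matrix
    Y = ds.intensities.to_numpy()
    observed_mask = ~np.isnan(Y)

    fits: dict[str, PeptideFit] = {}
    skipped: dict[str, str] = {}
    for j, fid in enumerate(ds.feature_ids):
        o_j = np.flatnonzero(observed_mask[j])
        if o_j.size == 0:
            skipped[fid] = "no observed cells"
            continue
        s_j = subset_model(design, o_j)
        n_over_p = o_j.size / s_j.size
        if n_over_p <= 1:
            skipped[fid] = f"n/p = {n_over_p:.3g} <= 1"
            continue
        if n_over_p < np_threshold:
            skipped[fid] = f"n/p = {n_over_p:.3g} < threshold {np_threshold}"
            continue
        try:
            fits[fid] = fit_peptide(
                Y[j, o_j],
                X[np.ix_(o_j, s_j)],
                ridge_lambda=spec.ridge_lambda,
                feature_id=fid,
                observed=o_j,
                retained=s_j,
            )
        except np.linalg.LinAlgError as err:
            skipped[fid] = f"fit failure: {err}"
    return ModelResult(
        design=design,
        spec=spec,
        fits=fits,
        skipped=skipped,
        feature_annotations=ds.feature_annotations.loc[list(fits)].copy()
        if len(ds.feature_annotations.columns)
        else pd.DataFrame(index=pd.Index(list(fits))),
        cell_annotations=annotations,
    )


def effect_matrix(result: ModelResult, variable: str) -> pd.DataFrame:
    """Features×cells effect matrix M̂^(f) of one model variable.

    Entry (j, i) = Σ_{k ∈ K_f ∩ S_j} X[i, k]·β̂[k] for observed cells,
    NaN otherwise. ``variable`` may also be ``"intercept"`` or
    ``"residuals"`` (alias ``"residual"``).
    """
    design = result.design
    n_cells = design.matrix.shape[0]
    out = np.full((len(result.fits), n_cells), np.nan)

    if variable in ("residuals", "residual"):
        for j, fit in enumerate(result.fits.values()):
            out[j, fit.observed] = fit.residuals
    else:
        if variable == "intercept":
            k_f = np.array([design.intercept_index])
        elif variable in design.variable_columns:
            k_f = design.variable_columns[variable]
        else:
            raise KeyError(f"unknown model variable {variable!r}")
        for j, fit in enumerate(result.fits.values()):
            cols_mask = np.isin(fit.retained, k_f)
            if cols_mask.any():
                contrib = (
                    design.matrix[np.ix_(fit.observed, fit.retained[cols_mask])]
                    @ fit.coefficients[cols_mask]
                )
            else:
                contrib = np.zeros(fit.observed.size)  # variable fully dropped
            out[j, fit.observed] = contrib
    return pd.DataFrame(out, index=list(result.fits), columns=result.cell_ids)


def batch_corrected(
    result: ModelResult, keep: Sequence[str] = ()
) -> pd.DataFrame:
    """Batch-corrected reconstruction: intercept + retained effects + residuals.

    Technical effect matrices not listed in ``keep`` are discarded; the
    missing-value pattern of the input is preserved. ``keep`` is typically
    the biological variables (e.g. cell type).
    """
    unknown = [f for f in keep if f not in result.design.variable_columns]
    if unknown:
        raise KeyError(f"unknown model variables {unknown}")
    out = effect_matrix(result, "intercept") + effect_matrix(result, "residuals")
    for f in keep:
        out = out + effect_matrix(result, f)
    return out
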