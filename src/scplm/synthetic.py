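"""Synthetic single-cell proteomics data with known ground truth.

The generator emulates the structure of multiplexed SCP experiments on the
log2 scale: per-peptide baseline intensities, cell-type fold changes,
MS-acquisition-run batch effects, label-channel effects, per-cell size
factors, Gaussian residual noise, and two missingness mechanisms — MCAR
plus structural run dropout (a peptide entirely absent from a run, the
pattern that forces per-peptide design subsetting). Intensity-dependent
(MNAR) missingness is deliberately not simulated.

Every categorical effect family is re-centered to sum to zero, so the
truth is exactly expressible in the sum-contrast design encoding used by
the modeling module and "true log fold change" between two groups is
well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import ScpDataset
from .differential import vcov_ridge
from .modeling import ModelResult

__all__ = ["SimulationConfig", "SimulationTruth", "simulate", "evaluate_recovery"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated data set (log2-scale peptide level).

    Defaults describe a modest multiplexed experiment: 200 cells across 4
    MS runs with 3 label channels and 2 cell types; baselines N(7, 1) in
    log2 units; technical (run) effects dominating biological ones, as is
    typical for this kind of data.
    """

    n_cells: int = 200
    n_peptides: int = 300
    n_proteins: int = 100
    n_runs: int = 4
    n_labels: int = 3
    n_cell_types: int = 2
    celltype_scale: float = 0.5
    run_scale: float = 1.0
    label_scale: float = 0.2
    baseline_mean: float = 7.0
    baseline_scale: float = 1.0
    residual_sd: float = 0.5
    size_factor_sd: float = 0.2
    mcar_rate: float = 0.3
    run_dropout_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_peptides", "n_proteins", "n_runs",
                     "n_labels", "n_cell_types"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_proteins > self.n_peptides:
            raise ValueError("need at least one peptide per protein")
        for name in ("mcar_rate", "run_dropout_rate"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in [0, 1)")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated data set.

    ``coefficients`` is a peptides×parameters DataFrame aligned with the
    sum-contrast design the modeling module builds from the simulated
    descriptors (intercept + run + label + celltype, lexicographic level
    order); the dropped last level of each family equals minus the sum of
    the stored columns.
    """

    coefficients: pd.DataFrame
    residual_sd: float
    cell_annotations: pd.DataFrame
    size_factors: pd.Series
    run_dropout: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)


def _centered_effects(rng: np.random.Generator, n_peptides: int, n_levels: int,
                      scale: float) -> np.ndarray:
    """Per-peptide effects for one categorical family, sum-to-zero by row."""
    eff = rng.normal(0.0, scale, size=(n_peptides, n_levels)) if scale > 0 \
        else np.zeros((n_peptides, n_levels))
    return eff - eff.mean(axis=1, keepdims=True)


def simulate(config: SimulationConfig) -> tuple[ScpDataset, SimulationTruth]:
    """Draw one peptide×cell log2 data set plus its ground truth.

    Deterministic given ``config.seed``. Cells are assigned to runs in
    contiguous blocks (as in acquisition order), labels cycle within a
    run, and cell types are drawn uniformly.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_cells, config.n_peptides

    run_of = np.repeat(np.arange(config.n_runs),
                       int(np.ceil(n / config.n_runs)))[:n]
    label_of = np.concatenate([
        np.arange(np.sum(run_of == r)) % config.n_labels
        for r in range(config.n_runs)
    ])
    type_of = rng.integers(0, config.n_cell_types, size=n)
    size_factors = (rng.normal(0.0, config.size_factor_sd, size=n)
                    if config.size_factor_sd > 0 else np.zeros(n))

    baselines = rng.normal(config.baseline_mean, config.baseline_scale, size=m)
    run_eff = _centered_effects(rng, m, config.n_runs, config.run_scale)
    label_eff = _centered_effects(rng, m, config.n_labels, config.label_scale)
    type_eff = _centered_effects(rng, m, config.n_cell_types,
                                 config.celltype_scale)
    noise = (rng.normal(0.0, config.residual_sd, size=(m, n))
             if config.residual_sd > 0 else np.zeros((m, n)))

    y = (
        baselines[:, None]
        + size_factors[None, :]
        + run_eff[:, run_of]
        + label_eff[:, label_of]
        + type_eff[:, type_of]
        + noise
    )

    # missingness: MCAR, then whole-run dropout per peptide
    mask = rng.random(size=(m, n)) < config.mcar_rate
    dropout = rng.random(size=(m, config.n_runs)) < config.run_dropout_rate
    for r in range(config.n_runs):
        mask[np.ix_(dropout[:, r], run_of == r)] = True
    if mask.all():
        raise ValueError("configuration leaves no observed entries")
    y = np.where(mask, np.nan, y)

    peptide_ids = [f"pep{j:04d}" for j in range(m)]
    cell_ids = [f"cell{i:04d}" for i in range(n)]
    protein_of = np.arange(m) % config.n_proteins
    feature_annotations = pd.DataFrame(
        {"protein": [f"prot{q:04d}" for q in protein_of]}, index=peptide_ids
    )
    cell_annotations = pd.DataFrame(
        {
            "celltype": [f"type{t}" for t in type_of],
            "run": [f"run{r:02d}" for r in run_of],
            "label": [f"label{l}" for l in label_of],
        },
        index=cell_ids,
    )

    ds = ScpDataset(
        intensities=pd.DataFrame(y, index=peptide_ids, columns=cell_ids),
        feature_annotations=feature_annotations,
        cell_annotations=cell_annotations,
        level="peptide",
        log_transformed=True,
    )

    # truth aligned with the sum-contrast encoding (first a−1 levels kept)
    coef_cols: dict[str, np.ndarray] = {"intercept": baselines}
    for fam, eff, levels in (
        ("run", run_eff, [f"run{r:02d}" for r in range(config.n_runs)]),
        ("label", label_eff, [f"label{l}" for l in range(config.n_labels)]),
        ("celltype", type_eff, [f"type{t}" for t in range(config.n_cell_types)]),
    ):
        for i, lev in enumerate(levels[:-1]):
            coef_cols[f"{fam}[{lev}]"] = eff[:, i]
    truth = SimulationTruth(
        coefficients=pd.DataFrame(coef_cols, index=peptide_ids),
        residual_sd=config.residual_sd,
        cell_annotations=cell_annotations,
        size_factors=pd.Series(size_factors, index=cell_ids),
        run_dropout=pd.DataFrame(
            dropout, index=peptide_ids,
            columns=[f"run{r:02d}" for r in range(config.n_runs)],
        ),
        config=config,
    )
    return ds, truth


def evaluate_recovery(
    truth: SimulationTruth,
    result: ModelResult,
    level: float = 0.95,
) -> pd.DataFrame:
    """Coefficient-recovery report per effect family.

    For every fitted peptide and every retained parameter of each family
    (including the intercept), the estimate is compared with the truth:
    the report carries bias (mean error), RMSE, and the fraction of
    t_ν-based confidence intervals covering the true value.
    """
    from scipy import stats

    design = result.design
    lam = result.spec.ridge_lambda
    families = ["intercept"] + [
        v for v in result.variables if v in ("run", "label", "celltype")
    ]
    missing = [v for v in result.variables
               if v not in ("run", "label", "celltype", "median_intensity")]
    if missing:
        raise KeyError(f"model variables without simulated truth: {missing}")

    errors: dict[str, list[float]] = {f: [] for f in families}
    covered: dict[str, list[bool]] = {f: [] for f in families}
    for fid, fit in result.fits.items():
        x_sub = result.design_for(fit)
        vcov = vcov_ridge(fit, x_sub, lam)
        se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
        tcrit = stats.t.ppf(0.5 + level / 2.0, fit.df_residual)
        for fam in families:
            k_f = (np.array([design.intercept_index]) if fam == "intercept"
                   else design.variable_columns[fam])
            for pos, k in enumerate(fit.retained):
                if k not in k_f:
                    continue
                name = design.parameter_names[k]
                if name not in truth.coefficients.columns:
                    continue
                true_val = truth.coefficients.loc[fid, name]
                err = fit.coefficients[pos] - true_val
                errors[fam].append(err)
                covered[fam].append(abs(err) <= tcrit * se[pos])

    rows = []
    for fam in families:
        e = np.asarray(errors[fam])
        rows.append(
            dict(
                family=fam,
                n=e.size,
                bias=float(e.mean()) if e.size else np.nan,
                rmse=float(np.sqrt((e ** 2).mean())) if e.size else np.nan,
                coverage=float(np.mean(covered[fam])) if e.size else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=["family", "n", "bias", "rmse", "coverage"])
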