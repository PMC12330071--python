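"""Differential abundance analysis on the per-peptide ridge fits.

Inference follows the ridge sandwich variance-covariance estimator

    V(β̂) = (XᵀX + λI)⁻¹ XᵀX (XᵀX + λI)⁻¹ σ̂²,

with contrast t-statistics T = Lβ̂ / √(L V Lᵀ) referred to a t
distribution on ν = |O_j| − |S_j| degrees of freedom. Multiple testing is
adjusted either by Benjamini-Hochberg or by a binned independent-
hypothesis-weighting scheme that learns mean-one weights from the
baseline (intercept) intensity: high-baseline peptides are less noisy and
are penalized less. Peptide p-values can be combined to the protein level
with seven classical methods; the protein log fold change is that of the
representative peptide driving the combined statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .modeling import DesignMatrix, ModelResult, PeptideFit

__all__ = [
    "ContrastMatrix",
    "build_contrast",
    "vcov_ridge",
    "test_contrasts",
    "adjust_pvalues",
    "combine_to_protein",
    "PROTEIN_METHODS",
]


@dataclass(frozen=True)
class ContrastMatrix:
    """Contrast rows L (c×p) over a design's parameter columns."""

    matrix: np.ndarray
    names: tuple[str, ...]
    parameter_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.names):
            raise ValueError("contrast matrix shape does not match names")


def build_contrast(
    design: DesignMatrix, variable: str, group_a, group_b
) -> ContrastMatrix:
    """Group-difference contrast a − b of a sum-coded categorical variable.

    The row equals encoding(group_a) − encoding(group_b) on the variable's
    K_f columns and zero elsewhere, so Lβ̂ is the model-implied mean
    difference (a log2 fold change on log2 data).
    """
    if variable not in design.level_order:
        raise KeyError(f"{variable!r} is not a categorical model variable")
    row = np.zeros(design.n_parameters)
    k_f = design.variable_columns[variable]
    row[k_f] = design.encoding_row(variable, group_a) - design.encoding_row(
        variable, group_b
    )
    return ContrastMatrix(
        matrix=row[None, :],
        names=(f"{variable}:{group_a}-{group_b}",),
        parameter_names=tuple(design.parameter_names),
    )


def vcov_ridge(
    fit: PeptideFit, x_sub: np.ndarray, ridge_lambda: float
) -> np.ndarray:
    """Sandwich variance-covariance of the ridge coefficients (|S_j|×|S_j|)."""
    p = x_sub.shape[1]
    xtx = x_sub.T @ x_sub
    try:
        a_inv = linalg.solve(xtx + ridge_lambda * np.eye(p), np.eye(p),
                             assume_a="pos")
    except linalg.LinAlgError:
        return np.full((p, p), np.nan)
    v = a_inv @ xtx @ a_inv * fit.sigma2
    return (v + v.T) / 2.0  # symmetrize against round-off


def test_contrasts(result: ModelResult, contrast: ContrastMatrix) -> pd.DataFrame:
    """t-tests of each contrast for every fitted peptide.

    A peptide is non-estimable for a contrast when the contrast loads on a
    parameter dropped from S_j (e.g. the peptide was observed in only one
    of the compared groups); such rows are reported with NaN estimate and
    p-value rather than silently removed.
    """
    design = result.design
    lam = result.spec.ridge_lambda
    intercept = design.intercept_index
    rows = []
    for fid, fit in result.fits.items():
        x_sub = result.design_for(fit)
        vcov = None
        baseline = float(
            fit.coefficients[np.flatnonzero(fit.retained == intercept)[0]]
        )
        for name, l_full in zip(contrast.names, contrast.matrix):
            needed = np.flatnonzero(np.abs(l_full) > 0)
            estimable = np.isin(needed, fit.retained).all()
            if estimable:
                if vcov is None:
                    vcov = vcov_ridge(fit, x_sub, lam)
                estimable = np.all(np.isfinite(vcov))
            if not estimable or fit.df_residual < 1:
                rows.append(
                    dict(feature=fid, contrast=name, estimate=np.nan, se=np.nan,
                         t=np.nan, df=fit.df_residual, p=np.nan,
                         baseline=baseline, estimable=False)
                )
                continue
            l_sub = l_full[fit.retained]
            est = float(l_sub @ fit.coefficients)
            var = float(l_sub @ vcov @ l_sub)
            se = np.sqrt(max(var, 0.0))
            t = est / se if se > 0 else np.nan
            p = 2.0 * stats.t.sf(abs(t), fit.df_residual) if np.isfinite(t) else np.nan
            rows.append(
                dict(feature=fid, contrast=name, estimate=est, se=se, t=t,
                     df=fit.df_residual, p=p, baseline=baseline, estimable=True)
            )
    return pd.DataFrame(
        rows, columns=["feature", "contrast", "estimate", "se", "t", "df",
                       "p", "baseline", "estimable"]
    )


# -- multiple testing --------------------------------------------------------

def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _weighted_bh(p: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """BH on p/w with mean-one weights (zero weight → never rejected)."""
    with np.errstate(divide="ignore"):
        scaled = np.where(weights > 0, p / weights, np.inf)
    return np.minimum(_bh(np.minimum(scaled, 1.0)), 1.0)


def _bh_discoveries(p: np.ndarray, weights: np.ndarray, alpha: float) -> int:
    return int((_weighted_bh(p, weights) <= alpha).sum())


def adjust_pvalues(
    inferences: pd.DataFrame,
    method: str = "bh",
    n_bins: int = 5,
    alpha: float = 0.05,
    n_candidates: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Add an ``adjusted_p`` column, per contrast.

    ``method="bh"`` is plain Benjamini-Hochberg. ``method="ihw-binned"``
    stratifies estimable tests into ``n_bins`` quantile bins of baseline
    intensity and learns per-bin weights by 2-fold cross-weighting: each
    fold's weights are chosen on the complementary fold (random search
    over mean-one weight vectors, maximizing BH discoveries at ``alpha``),
    then a single weighted BH is applied. Falls back to plain BH when
    fewer than ``10 * n_bins`` estimable tests are available.
    """
    if method not in ("bh", "ihw-binned"):
        raise ValueError(f"unknown adjustment method {method!r}")
    out = inferences.copy()
    out["adjusted_p"] = np.nan
    for _, idx in out.groupby("contrast", sort=False).groups.items():
        sub = out.loc[idx]
        ok = sub["p"].notna()
        if not ok.any():
            continue
        p = sub.loc[ok, "p"].to_numpy()
        if method == "bh" or ok.sum() < 10 * n_bins:
            adj = _bh(p)
        else:
            baseline = sub.loc[ok, "baseline"].to_numpy()
            bins = np.minimum(
                np.searchsorted(
                    np.quantile(baseline, np.linspace(0, 1, n_bins + 1)[1:-1]),
                    baseline, side="right"),
                n_bins - 1,
            )
            rng = np.random.default_rng(seed)
            folds = rng.integers(0, 2, size=p.size)
            weights = np.ones(p.size)
            for fold in (0, 1):
                train = folds != fold
                best, best_n = np.ones(n_bins), _bh_discoveries(
                    p[train], np.ones(train.sum()), alpha
                )
                for _ in range(n_candidates):
                    cand = rng.dirichlet(np.ones(n_bins)) * n_bins
                    n_disc = _bh_discoveries(p[train], cand[bins[train]], alpha)
                    if n_disc > best_n:
                        best, best_n = cand, n_disc
                weights[folds == fold] = best[bins[folds == fold]]
            weights = weights / weights.mean()
            adj = _weighted_bh(p, weights)
        out.loc[sub.index[ok], "adjusted_p"] = adj
    return out


# -- protein-level combination ----------------------------------------------

def _fisher(p: np.ndarray) -> tuple[float, int]:
    stat = -2.0 * np.sum(np.log(np.maximum(p, 1e-300)))
    return float(stats.chi2.sf(stat, 2 * p.size)), int(np.argmin(p))


def _pearson(p: np.ndarray) -> tuple[float, int]:
    stat = -2.0 * np.sum(np.log(np.maximum(1.0 - p, 1e-300)))
    return float(stats.chi2.cdf(stat, 2 * p.size)), int(np.argmin(p))


def _simes(p: np.ndarray) -> tuple[float, int]:
    order = np.argsort(p, kind="stable")
    scaled = p[order] * p.size / np.arange(1, p.size + 1)
    i = int(np.argmin(scaled))
    return float(min(scaled[i], 1.0)), int(order[i])


def _berger(p: np.ndarray) -> tuple[float, int]:
    i = int(np.argmax(p))
    return float(p[i]), i


def _holm_min(p: np.ndarray) -> tuple[float, int]:
    # Holm-adjusted p-values are non-decreasing, so their minimum is k·p_min.
    i = int(np.argmin(p))
    return float(min(p.size * p[i], 1.0)), i


def _stouffer(p: np.ndarray) -> tuple[float, int]:
    z = stats.norm.isf(np.clip(p, 1e-300, 1 - 1e-16))
    return float(stats.norm.sf(z.sum() / np.sqrt(p.size))), int(np.argmin(p))


def _wilkinson(p: np.ndarray) -> tuple[float, int]:
    # order statistic r = 1: P(min p <= x) under the global null
    i = int(np.argmin(p))
    return float(stats.beta.cdf(p[i], 1, p.size)), i


PROTEIN_METHODS = {
    "fisher": _fisher,
    "simes": _simes,
    "berger": _berger,
    "pearson": _pearson,
    "holm-min": _holm_min,
    "stouffer": _stouffer,
    "wilkinson": _wilkinson,
}


def combine_to_protein(
    inferences: pd.DataFrame,
    peptide_to_protein: pd.Series,
    method: str = "simes",
) -> pd.DataFrame:
    """Combine peptide p-values per protein; logFC = representative peptide's.

    The representative peptide is the one determining the combined
    statistic (min-p by convention, max-p for Berger); ties on p are
    broken by larger |estimate| then lexicographic peptide id. Proteins
    with no estimable peptide are skipped. Protein-level BH is applied
    across proteins within each contrast.
    """
    if method not in PROTEIN_METHODS:
        raise ValueError(f"unknown combination method {method!r}")
    combine = PROTEIN_METHODS[method]
    peptides = inferences["feature"].unique()
    unmapped = [pep for pep in peptides if pep not in peptide_to_protein.index]
    if unmapped:
        raise KeyError(f"peptides without protein mapping: {unmapped[:10]}")

    tagged = inferences.assign(
        protein=inferences["feature"].map(peptide_to_protein)
    )
    rows = []
    for (protein, contrast), grp in tagged.groupby(["protein", "contrast"],
                                                   sort=False):
        est = grp[grp["estimable"] & grp["p"].notna()]
        if est.empty:
            continue
        # deterministic representative under ties: p asc, |logFC| desc, id asc
        est = est.sort_values(
            by=["p", "estimate", "feature"],
            key=lambda s: -s.abs() if s.name == "estimate" else s,
            kind="stable",
        ).reset_index(drop=True)
        p_comb, rep = combine(est["p"].to_numpy())
        rows.append(
            dict(
                protein=protein,
                contrast=contrast,
                p=p_comb,
                representative=est.loc[rep, "feature"],
                logfc=est.loc[rep, "estimate"],
                n_peptides=len(est),
                method=method,
            )
        )
    out = pd.DataFrame(
        rows, columns=["protein", "contrast", "p", "representative", "logfc",
                       "n_peptides", "method"]
    )
    out["adjusted_p"] = np.nan
    for _, idx in out.groupby("contrast", sort=False).groups.items():
        out.loc[idx, "adjusted_p"] = _bh(out.loc[idx, "p"].to_numpy())
    return out
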