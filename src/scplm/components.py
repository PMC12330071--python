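"""APCA+ component analysis with missing-value-tolerant NIPALS PCA.

For a model variable f, the augmented effect matrix A^(f) = M̂^(f) + ε̂
(cells×features, missing where unobserved) carries that variable's
modeled effect on top of the residual heterogeneity. A^(f) is centered
feature-wise on the observed entries and decomposed as A ≈ S Vᵀ by
NIPALS, which extracts one component at a time using only observed
entries and therefore needs no imputation. Eigenvalues are the score
sums of squares (squared singular values on complete data).

Peptide loadings can be aggregated to protein loadings by the median;
this breaks orthogonality but gives a usable protein-level view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modeling import ModelResult, effect_matrix

__all__ = ["ComponentResult", "nipals", "apca", "protein_loadings"]


@dataclass
class ComponentResult:
    """Scores (cells×k), loadings (features×k) and eigenvalues of one APCA+ run."""

    variable: str
    scores: pd.DataFrame
    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    centering: pd.Series

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def _sign_fix(scores: np.ndarray, loadings: np.ndarray) -> None:
    """Deterministic sign convention: each loading vector's largest-magnitude
    element is made positive (scores flipped accordingly), in place."""
    for c in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[i, c] < 0:
            loadings[:, c] *= -1.0
            scores[:, c] *= -1.0


def _als_refine(
    a: np.ndarray,
    obs: np.ndarray,
    scores: np.ndarray,
    loadings: np.ndarray,
    tol: float,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint alternating-least-squares polish of a greedy NIPALS solution.

    Sequential extraction is only approximate when entries are missing
    (the mask breaks component orthogonality); alternating row-wise and
    column-wise least squares over the whole k-dimensional subspace
    converges to the best rank-k fit of the observed entries. The
    refined factors are re-orthogonalized via a k×k SVD in factored
    form, so loadings stay orthonormal and eigenvalues sorted.
    """
    n, m = a.shape
    k = scores.shape[1]
    s, v = scores.copy(), loadings.copy()
    prev = np.inf
    for _ in range(max_iter):
        for i in range(n):
            o = obs[i]
            s[i] = np.linalg.lstsq(v[o], a[i, o], rcond=None)[0]
        for j in range(m):
            o = obs[:, j]
            v[j] = np.linalg.lstsq(s[o], a[o, j], rcond=None)[0]
        sse = float(np.sum((a - s @ v.T)[obs] ** 2))
        if prev - sse <= tol * max(sse, 1.0):
            break
        prev = sse
    # re-orthogonalize: S Vᵀ = (Qs Rs)(Qv Rv)ᵀ = Qs (Rs Rvᵀ) Qvᵀ
    qs, rs = np.linalg.qr(s)
    qv, rv = np.linalg.qr(v)
    u_r, sing, vt_r = np.linalg.svd(rs @ rv.T)
    return qs @ u_r * sing, qv @ vt_r.T, sing ** 2


def nipals(
    a: np.ndarray,
    k: int,
    tol: float = 1e-9,
    max_iter: int = 500,
    refine: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NIPALS PCA of a (possibly incomplete) matrix.

    Components are extracted one at a time by power-style iteration on
    the observed entries with rank-1 deflation; when the matrix has
    missing entries the greedy solution is then polished by a joint
    alternating-least-squares pass over the extracted subspace
    (``refine=True``), which markedly improves the observed-entry
    reconstruction.

    Parameters
    ----------
    a
        cells×features array, NaN = missing. Assumed already centered;
        every row and column must have at least one observed entry.
    k
        Number of components requested; fewer are returned (with a
        warning) when the matrix rank is exhausted.

    Returns
    -------
    scores (n×k'), loadings (m×k'), eigenvalues (k',) with k' ≤ k,
    eigenvalues non-increasing.
    """
    a = np.array(a, dtype=float)
    n, m = a.shape
    obs = ~np.isnan(a)
    if not obs.any(axis=1).all() or not obs.any(axis=0).all():
        raise ValueError("NIPALS requires ≥1 observed entry per row and column")
    work = np.where(obs, a, 0.0)

    scores = np.zeros((n, k))
    loadings = np.zeros((m, k))
    eigenvalues = np.zeros(k)
    achieved = 0
    for comp in range(k):
        # start from the column with the largest observed variance
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_var = np.nanvar(np.where(obs, work, np.nan), axis=0)
        col_var = np.nan_to_num(col_var)
        if col_var.max() <= 1e-14:
            break  # rank exhausted
        t = work[:, int(np.argmax(col_var))].copy()
        p = np.zeros(m)
        for _ in range(max_iter):
            # loadings: regress each column on t over its observed entries
            tw = np.where(obs.T, t, 0.0)
            denom_p = (tw * tw).sum(axis=1)
            p_new = np.where(denom_p > 0, (work.T * tw).sum(axis=1) / denom_p, 0.0)
            norm = np.linalg.norm(p_new)
            if norm == 0:
                break
            p_new /= norm
            # scores: regress each row on p over its observed entries
            pw = np.where(obs, p_new[None, :], 0.0)
            denom_t = (pw * pw).sum(axis=1)
            t = np.where(denom_t > 0, (work * pw).sum(axis=1) / denom_t, 0.0)
            if np.linalg.norm(p_new - p) < tol:
                p = p_new
                break
            p = p_new
        # a component is accepted at tolerance or at the iteration cap;
        # slow power-iteration convergence (near-equal eigenvalues) is
        # resolved by the joint refinement pass
        if not np.all(np.isfinite(p)) or not np.all(np.isfinite(t)):
            raise RuntimeError(f"NIPALS diverged on component {comp + 1}")
        lam = float(t @ t)
        if lam <= 1e-14:
            break
        scores[:, comp] = t
        loadings[:, comp] = p
        eigenvalues[comp] = lam
        work = np.where(obs, work - np.outer(t, p), 0.0)
        achieved += 1

    if achieved < k:
        warnings.warn(
            f"requested {k} components, matrix rank allows {achieved}",
            RuntimeWarning,
            stacklevel=2,
        )
    scores = scores[:, :achieved]
    loadings = loadings[:, :achieved]
    eigenvalues = eigenvalues[:achieved]
    if refine and achieved and not obs.all():
        scores, loadings, eigenvalues = _als_refine(
            np.where(obs, a, 0.0), obs, scores, loadings, tol
        )
    order = np.argsort(-eigenvalues, kind="stable")
    scores, loadings = scores[:, order], loadings[:, order]
    eigenvalues = eigenvalues[order]
    _sign_fix(scores, loadings)
    return scores, loadings, eigenvalues


def apca(
    result: ModelResult,
    variable: str,
    k: int = 20,
    tol: float = 1e-9,
    max_iter: int = 500,
    dataset: pd.DataFrame | None = None,
) -> ComponentResult:
    """APCA+ decomposition of one model variable's augmented effect matrix.

    ``variable`` may be any model variable, ``"residual"`` (residuals
    only) or ``"unmodelled"`` (PCA of the processed data itself, the
    pre-modeling view; requires ``dataset`` = features×cells DataFrame).
    """
    if variable == "unmodelled":
        if dataset is None:
            raise ValueError("variable='unmodelled' requires the dataset matrix")
        a_df = dataset.T
    elif variable in ("residual", "residuals"):
        a_df = effect_matrix(result, "residuals").T
    else:
        a_df = (
            effect_matrix(result, variable) + effect_matrix(result, "residuals")
        ).T
    # cells×features orientation: cells are the score space
    center = a_df.mean(axis=0, skipna=True)
    centered = a_df - center
    scores, loadings, eigenvalues = nipals(
        centered.to_numpy(), k=k, tol=tol, max_iter=max_iter
    )
    total_var = float(np.nansum(centered.to_numpy() ** 2))
    names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return ComponentResult(
        variable=variable,
        scores=pd.DataFrame(scores, index=a_df.index, columns=names),
        loadings=pd.DataFrame(loadings, index=a_df.columns, columns=names),
        eigenvalues=eigenvalues,
        percent_variance=100.0 * eigenvalues / total_var if total_var > 0
        else np.zeros_like(eigenvalues),
        centering=center,
    )


def protein_loadings(
    cr: ComponentResult, peptide_to_protein: pd.Series
) -> pd.DataFrame:
    """Protein×k loadings: median of each protein's peptide loadings.

    The medians are no longer orthogonal between components; they are a
    pragmatic protein-level summary for exploration, not a rotation.
    """
    unmapped = [p for p in cr.loadings.index if p not in peptide_to_protein.index]
    if unmapped:
        raise KeyError(f"peptides without protein mapping: {unmapped[:10]}")
    return cr.loadings.groupby(
        cr.loadings.index.map(peptide_to_protein)
    ).median()
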