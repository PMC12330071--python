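"""Batch-correction benchmark: PCA → k-means → clustering/partition metrics.

A good batch correction separates biological groups (cell types) while
mixing technical groups (MS acquisition runs). The harness reduces the
corrected matrix with missing-value-tolerant NIPALS PCA, clusters cells
with k-means, and scores the clustering against the biological and
technical labels with ARI, NMI and purity; the average silhouette width
is computed on the PC scores directly against the known labels.
Technical scores are reported as 1 − metric, so that higher is always
better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_score,
)

from .components import nipals

__all__ = ["BenchmarkReport", "benchmark", "ari", "nmi", "purity", "asw"]


def _check_lengths(a, b) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"label lengths differ: {a.shape} vs {b.shape}")
    return a, b


def ari(a, b) -> float:
    """Adjusted Rand index (pair counting with expected-index correction)."""
    a, b = _check_lengths(a, b)
    return float(adjusted_rand_score(a, b))


def nmi(a, b) -> float:
    """Normalized mutual information, arithmetic-mean normalization."""
    a, b = _check_lengths(a, b)
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def purity(clusters, truth) -> float:
    """Purity score: Σ_c max_t |c ∩ t| / n (not symmetric in its arguments)."""
    clusters, truth = _check_lengths(clusters, truth)
    total = 0
    for c in np.unique(clusters):
        _, counts = np.unique(truth[clusters == c], return_counts=True)
        total += counts.max()
    return float(total / clusters.size)


def asw(points: np.ndarray, labels) -> float:
    """Average silhouette width of a labeled point cloud (Euclidean)."""
    labels = np.asarray(labels)
    points = np.asarray(points, dtype=float)
    if len(labels) != points.shape[0]:
        raise ValueError("labels and points disagree in length")
    if len(np.unique(labels)) < 2:
        raise ValueError("ASW needs at least two distinct labels")
    return float(silhouette_score(points, labels, metric="euclidean"))


@dataclass
class BenchmarkReport:
    """Biological-separation and technical-mixing scores of one matrix."""

    metrics: pd.DataFrame  # index: metric, columns: biological, one_minus_technical
    clusters: np.ndarray
    scores: pd.DataFrame
    n_pcs: int
    k: int

    def to_frame(self) -> pd.DataFrame:
        return self.metrics.copy()


def benchmark(
    corrected: pd.DataFrame,
    bio_labels,
    tech_labels,
    n_pcs: int = 20,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
) -> BenchmarkReport:
    """Score a (batch-corrected) features×cells matrix.

    NIPALS PCA (``n_pcs`` components, feature-wise centering on observed
    entries) followed by k-means on the scores (``n_restarts`` seeded
    restarts, best inertia kept). ARI/NMI/purity compare the clustering
    with each label set; ASW uses the known labels on the PC scores.
    """
    bio_labels = np.asarray(bio_labels)
    tech_labels = np.asarray(tech_labels)
    n_cells = corrected.shape[1]
    if len(bio_labels) != n_cells or len(tech_labels) != n_cells:
        raise ValueError("labels must cover all cells")
    if n_cells < k:
        raise ValueError(f"fewer cells ({n_cells}) than clusters ({k})")

    a = corrected.T  # cells×features
    centered = (a - a.mean(axis=0, skipna=True)).to_numpy()
    n_pcs = min(n_pcs, *centered.shape)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        scores, _, _ = nipals(centered, k=n_pcs)

    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    clusters = km.fit_predict(scores)

    rows = {}
    for name, fn in (("ARI", ari), ("NMI", nmi), ("PS", purity)):
        rows[name] = {
            "biological": fn(clusters, bio_labels),
            "one_minus_technical": 1.0 - fn(clusters, tech_labels),
        }
    rows["ASW"] = {
        "biological": asw(scores, bio_labels),
        "one_minus_technical": 1.0 - asw(scores, tech_labels),
    }
    metrics = pd.DataFrame(rows).T[["biological", "one_minus_technical"]]
    return BenchmarkReport(
        metrics=metrics,
        clusters=clusters,
        scores=pd.DataFrame(
            scores, index=corrected.columns,
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        ),
        n_pcs=scores.shape[1],
        k=k,
    )
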