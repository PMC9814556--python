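"""Species counting in congested elution windows.

In a window where peaks co-elute, each timepoint's spectrum is a convex
mixture of the underlying species spectra. After unit-norm scaling
(removing concentration magnitude), timepoints cluster by spectral
direction: PCA embeds them in a low-dimensional space and K-means with
the elbow criterion estimates the number of distinct species — including
species with no chromatographic apex of their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io import SpectralChromatogram, ValidationError

__all__ = ["ClusteringResult", "collect_window_spectra", "pca_embed", "estimate_k_elbow"]


@dataclass
class ClusteringResult:
    """Outcome of K-means species counting on PCA scores."""

    k: int
    labels: np.ndarray
    centers: np.ndarray
    wcss_curve: np.ndarray          # within-cluster sum of squares, k = 1..k_max
    scores: np.ndarray              # PCA coordinates per timepoint
    second_differences: np.ndarray = field(default_factory=lambda: np.empty(0))


def collect_window_spectra(
    chrom: SpectralChromatogram,
    t_start: float,
    t_end: float,
    min_absorbance: float | None = None,
) -> np.ndarray:
    """Per-timepoint spectra from a time window, unit-norm scaled.

    Rows whose total absorbance is below ``min_absorbance`` (default: 10%
    of the window's largest row total) are dropped as baseline-only —
    near-baseline rows have noise-dominated spectral directions that
    blur the cluster structure.
    Fewer than 5 surviving rows is an error — the window is too sparse
    for clustering.
    """
    mask = (chrom.time >= t_start) & (chrom.time <= t_end)
    if not mask.any():
        raise ValidationError("window outside time axis")
    rows = chrom.absorbance[mask]
    totals = rows.sum(axis=1)
    if min_absorbance is None:
        min_absorbance = 0.10 * float(totals.max()) if totals.max() > 0 else np.inf
    keep = totals >= min_absorbance
    rows = rows[keep]
    if rows.shape[0] < 5:
        raise ValidationError(
            f"window too sparse: {rows.shape[0]} spectra above threshold (need >= 5)"
        )
    norms = np.linalg.norm(rows, axis=1, keepdims=True)
    return rows / norms


def pca_embed(spectra_matrix: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centred projection onto the leading principal components.

    Returns ``(scores, explained_variance_ratio)``. Component signs follow
    a deterministic convention: the largest-magnitude loading of each
    component is positive.
    """
    X = np.asarray(spectra_matrix, dtype=float)
    if X.shape[0] < n_components + 1:
        raise ValidationError(
            f"need at least {n_components + 1} spectra for {n_components} components"
        )
    if np.allclose(X, X[0], atol=1e-12):
        raise ValidationError("degenerate input: all spectra identical (zero variance)")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    return scores, pca.explained_variance_ratio_


def estimate_k_elbow(
    scores: np.ndarray,
    k_max: int = 8,
    n_restarts: int = 10,
    seed: int = 0,
    noise_floor: float = 0.05,
) -> ClusteringResult:
    """Choose the cluster count by the elbow of the WCSS curve.

    K-means is run for k = 1..k_max (best of ``n_restarts`` each); the
    elbow is the k maximising the discrete second difference
    ``wcss(k−1) − 2·wcss(k) + wcss(k+1)`` over k = 2..k_max−1, ties
    broken toward smaller k (parsimony). If wcss(1) is already below
    ``noise_floor`` × total squared norm the window is effectively
    single-species and k = 1 is returned directly.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < k_max:
        raise ValidationError(f"need at least k_max={k_max} points, got {n}")
    total_ss = float(n)  # unit-norm rows: uncentred squared norm per row is 1
    wcss = np.empty(k_max)
    fits = []
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        km.fit(X)
        wcss[k - 1] = km.inertia_
        fits.append(km)
    # enforce monotone non-increasing curve (restarts can leave tiny inversions)
    wcss = np.minimum.accumulate(wcss)
    if wcss[0] < noise_floor * total_ss:
        km = fits[0]
        return ClusteringResult(
            k=1, labels=km.labels_, centers=km.cluster_centers_, wcss_curve=wcss, scores=X
        )
    # second differences at k = 2..k_max-1
    d2 = wcss[:-2] - 2.0 * wcss[1:-1] + wcss[2:]
    k_best = int(np.argmax(d2)) + 2  # ties: argmax takes the first (smallest k)
    km = fits[k_best - 1]
    return ClusteringResult(
        k=k_best,
        labels=km.labels_,
        centers=km.cluster_centers_,
        wcss_curve=wcss,
        scores=X,
        second_differences=d2,
    )
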