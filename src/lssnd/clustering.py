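"""Unsupervised analysis of preprocessed spectra.

PCA projection for variance reporting and visualization, graph spectral
clustering (Gaussian affinity on Euclidean distances, symmetric normalized
Laplacian, k-means on the spectral embedding), eigengap selection of the
cluster count, association of clusters with nuclear density, and the
one-way ANOVA / Tukey-Kramer group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass(frozen=True)
class PCAResult:
    component_scores: np.ndarray            # (n_spectra, n_components)
    explained_variance_fractions: np.ndarray

    def top_k_fraction(self, k: int) -> float:
        return float(self.explained_variance_fractions[:k].sum())


@dataclass
class ClusterAssignment:
    labels: np.ndarray                       # cluster ids 1..k per spectrum
    n_clusters: int
    laplacian_eigenvalues: np.ndarray        # ascending
    nd_summary: dict | None = None           # cluster id -> (mean, sd, n)


@dataclass(frozen=True)
class GroupComparison:
    F_statistic: float
    p_value: float
    significant_pairs: tuple[tuple[int, int], ...]
    alpha: float = 0.05


def pca_project(spectra: np.ndarray) -> PCAResult:
    """Mean-centered PCA of a (n_spectra, n_features) matrix."""
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 spectra")
    pca = PCA(n_components=min(X.shape))
    scores = pca.fit_transform(X)
    return PCAResult(scores, pca.explained_variance_ratio_.copy())


def _local_scales(dist: np.ndarray) -> np.ndarray:
    """Per-point affinity scales: distance to the m-th nearest neighbour.

    m grows with the dataset (about a tenth of it, at least 5), so each
    point's scale reflects its own neighbourhood density.  Locally scaled
    affinities keep within-group weights of order one for tight and loose
    groups alike while distant groups decouple, independently of the feature
    dimension.
    """
    n = dist.shape[0]
    m = min(max(5, int(round(0.09 * n))), n - 1)
    scales = np.partition(dist, m, axis=1)[:, m]
    floor = dist[dist > 0].min() if np.any(dist > 0) else 1.0
    return np.maximum(scales, 1e-12 * floor + 1e-300)


def spectral_cluster(spectra: np.ndarray, k: int, seed: int = 0,
                     kernel_scale: float | str = "auto",
                     standardize: bool = False) -> ClusterAssignment:
    """Graph spectral clustering of spectra into k groups.

    Pairwise Euclidean distances on the spectra (mean-normalized traces are
    already on a common intensity scale; optional per-feature standardization
    is available but amplifies noise-dominated features) enter a Gaussian
    affinity: with ``kernel_scale="auto"`` the locally
    scaled form exp(-d_ij^2 / (sigma_i sigma_j)) with sigma_i the distance to
    the m-th nearest neighbour, otherwise exp(-d^2 / (2 sigma^2)) at the
    given fixed sigma.  The symmetric normalized Laplacian's k smallest
    eigenvectors are row-normalized and clustered by seeded k-means with 10
    restarts.  All Laplacian eigenvalues are returned for eigengap model
    selection.
    """
    X = np.asarray(spectra, dtype=float)
    n = X.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must be in [2, {n - 1}]")
    if standardize:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    D = squareform(pdist(X))
    if kernel_scale == "auto":
        s = _local_scales(D)
        A = np.exp(-(D ** 2) / np.outer(s, s))
    else:
        sigma = float(kernel_scale)
        A = np.exp(-(D ** 2) / (2.0 * sigma ** 2))
    np.fill_diagonal(A, 0.0)
    deg = A.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    L = np.eye(n) - inv_sqrt[:, None] * A * inv_sqrt[None, :]
    eigvals, eigvecs = np.linalg.eigh(L)
    U = eigvecs[:, :k]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    U = U / np.where(norms > 0, norms, 1.0)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(U)
    return ClusterAssignment(labels=km.labels_ + 1, n_clusters=k,
                             laplacian_eigenvalues=eigvals)


def estimate_cluster_count(laplacian_eigenvalues: np.ndarray,
                           k_max: int = 10) -> int:
    """Eigengap heuristic: argmax over k in [2, k_max] of lam_{k+1} - lam_k."""
    lam = np.asarray(laplacian_eigenvalues, dtype=float)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if lam.size < k_max + 1:
        raise ValueError(f"need at least {k_max + 1} eigenvalues")
    if np.any(np.diff(lam) < -1e-9):
        raise ValueError("eigenvalues must be sorted ascending")
    gaps = lam[2:k_max + 1] - lam[1:k_max]   # gap after lam_k, k = 2..k_max
    return int(np.argmax(gaps)) + 2


def associate_clusters_with_nd(assignment: ClusterAssignment,
                               nd_values: np.ndarray) -> ClusterAssignment:
    """Relabel clusters 1..k in order of increasing mean ND; fill summaries."""
    nd = np.asarray(nd_values, dtype=float)
    if nd.shape[0] != assignment.labels.shape[0]:
        raise ValueError("every spectrum needs an ND annotation")
    if np.any(~np.isfinite(nd)):
        raise ValueError("missing (non-finite) ND annotation")
    old_ids = np.unique(assignment.labels)
    means = {c: nd[assignment.labels == c].mean() for c in old_ids}
    order = sorted(old_ids, key=lambda c: means[c])
    remap = {old: new + 1 for new, old in enumerate(order)}
    new_labels = np.array([remap[c] for c in assignment.labels])
    summary = {}
    for c in sorted(remap.values()):
        vals = nd[new_labels == c]
        summary[c] = {"mean": float(vals.mean()),
                      "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                      "n": int(vals.size)}
    return replace(assignment, labels=new_labels, nd_summary=summary)


def count_miscategorized(assignment: ClusterAssignment,
                         sample_ids: np.ndarray) -> int:
    """Spectra not in their source sample's majority cluster.

    For each sample the majority cluster is found (ties broken toward the
    lower cluster id); the return value is the number of spectra assigned to
    any other cluster.
    """
    sids = np.asarray(sample_ids)
    if sids.shape[0] != assignment.labels.shape[0]:
        raise ValueError("every spectrum needs a sample id")
    mis = 0
    for sid in np.unique(sids):
        labels = assignment.labels[sids == sid]
        ids, counts = np.unique(labels, return_counts=True)
        majority = ids[np.argmax(counts)]  # first max -> lowest cluster id
        mis += int(np.sum(labels != majority))
    return mis


def anova_tukey(groups: list[np.ndarray], alpha: float = 0.05
                ) -> GroupComparison:
    """One-way ANOVA with Tukey-Kramer post-hoc pairwise comparisons.

    Groups are lists of ND values; pairs of group indices whose means differ
    at level ``alpha`` are reported.  Tukey-Kramer (the unequal-n form of
    Tukey's HSD) comes from statsmodels.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    values = np.concatenate(arrays)
    codes = np.concatenate([np.full(a.size, i) for i, a in enumerate(arrays)])
    if np.ptp(values) == 0:
        return GroupComparison(0.0, 1.0, (), alpha)
    F, p = stats.f_oneway(*arrays)
    res = pairwise_tukeyhsd(values, codes, alpha=alpha)
    # statsmodels orders pairs as combinations of the sorted unique codes
    pairs = [(int(a), int(b)) for i, a in enumerate(res.groupsunique)
             for b in res.groupsunique[i + 1:]]
    sig = tuple(p_ for p_, rej in zip(pairs, np.asarray(res.reject)) if rej)
    return GroupComparison(float(F), float(p), sig, alpha)


def plot_pc_scatter(pca: PCAResult, assignment: ClusterAssignment, path=None):
    """Scatter of the first two PCs colored by cluster (optional helper)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for c in np.unique(assignment.labels):
        sel = assignment.labels == c
        ax.scatter(pca.component_scores[sel, 0], pca.component_scores[sel, 1],
                   s=8, label=f"cluster {c}")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=7)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
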