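"""Spectral clustering of the window dissimilarity matrix.

Pipeline: symmetrized k-nearest-neighbor affinity graph (binary weights, the
smallest neighbor count that connects the graph), unnormalized graph
Laplacian L = Deg - W, eigengap selection of the cluster count, k-means on
the first-k eigenvector rows, and severity ordering of the resulting classes
by mean raw glucose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.cluster import KMeans

from glucotyper.distance import DissimilarityMatrix
from glucotyper.preprocess import GlucoseWindow

SEVERITY_ORDER = ("low", "moderate", "severe")

_ZERO_EIG_TOL = 1e-8


@dataclass
class AffinityGraph:
    """Binary symmetric kNN adjacency over windows (diagonal zero)."""

    ids: list[str]
    w: np.ndarray
    n_neighbors: int

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class ClusterModel:
    """Trained spectral-clustering artifacts needed for out-of-sample use.

    embedding holds the first-k unnormalized-Laplacian eigenvector rows of
    the training windows; train_mean / train_sd are the global mg/dL scaling
    constants for new windows; sigma is the affinity kernel scale estimated
    on the full training dissimilarity matrix.
    """

    k: int
    ids: list[str]
    embedding: np.ndarray  # W x k
    centroids: np.ndarray  # k x k
    labels: np.ndarray  # cluster index per training window
    severity_order: dict[int, str]  # cluster index -> class name
    train_mean: float
    train_sd: float
    sigma: float
    n_neighbors: int
    band_fraction: float
    windows: list[GlucoseWindow] = field(default_factory=list, repr=False)
    eigenvalues: np.ndarray | None = None

    def class_of(self, cluster_index: int) -> str:
        return self.severity_order[int(cluster_index)]

    @property
    def class_labels(self) -> np.ndarray:
        """Severity class name per training window."""
        return np.array([self.severity_order[int(c)] for c in self.labels])


def _laplacian(w: np.ndarray) -> sp.csr_matrix:
    w = sp.csr_matrix(w)
    deg = np.asarray(w.sum(axis=1)).ravel()
    return sp.diags(deg) - w


def _smallest_eigs(L: sp.spmatrix, k: int, need_vectors: bool = False):
    """Smallest-k eigenpairs of the (PSD) unnormalized Laplacian."""
    n = L.shape[0]
    if k >= n - 1 or n <= 200:
        dense = L.toarray() if sp.issparse(L) else np.asarray(L)
        vals, vecs = np.linalg.eigh(dense)
        return (vals[:k], vecs[:, :k]) if need_vectors else (vals[:k], None)
    # shift-invert around a slightly negative pole: robust for singular PSD L
    vals, vecs = spla.eigsh(L.tocsc(), k=k, sigma=-1e-3, which="LM")
    order = np.argsort(vals)
    vals, vecs = vals[order], vecs[:, order]
    return (vals, vecs) if need_vectors else (vals, None)


def knn_affinity(D: DissimilarityMatrix, n: int) -> AffinityGraph:
    """Symmetrized n-nearest-neighbor graph with unit weights.

    Edge (i, j) exists iff j is among the n nearest of i or vice versa. Ties
    at the n-th neighbor are broken by window position (id order), so the
    graph is deterministic.
    """
    W = len(D)
    if not (1 <= n <= W - 1):
        raise ValueError(f"n must be in [1, {W - 1}], got {n}")
    d = D.d
    w = np.zeros((W, W), dtype=float)
    cols = np.arange(W)
    for i in range(W):
        # stable lexicographic order (distance, index) breaks ties by id order
        order = np.lexsort((cols, d[i]))
        order = order[order != i][:n]
        w[i, order] = 1.0
    w = np.maximum(w, w.T)
    np.fill_diagonal(w, 0.0)
    return AffinityGraph(ids=list(D.ids), w=w, n_neighbors=n)


def n_components(graph: AffinityGraph, tol: float = _ZERO_EIG_TOL) -> int:
    """Number of connected components = number of ~zero Laplacian eigenvalues."""
    L = _laplacian(graph.w)
    probe = min(len(graph), 12)
    while True:
        vals, _ = _smallest_eigs(L, probe)
        nz = int(np.sum(vals < tol))
        if nz < probe or probe >= len(graph):
            return max(nz, 1)
        probe = min(len(graph), probe * 2)


def is_connected(graph: AffinityGraph, tol: float = _ZERO_EIG_TOL) -> bool:
    """Connectivity via the spectrum: exactly one zero Laplacian eigenvalue."""
    L = _laplacian(graph.w)
    vals, _ = _smallest_eigs(L, min(2, L.shape[0]))
    if L.shape[0] == 1:
        return True
    return bool(vals[0] < tol < vals[1])


def min_connected_neighbors(D: DissimilarityMatrix) -> int:
    """Smallest n whose symmetrized kNN graph is connected (spectral check)."""
    W = len(D)
    if W < 2:
        raise ValueError("need at least 2 windows")
    for n in range(1, W):
        if is_connected(knn_affinity(D, n)):
            return n
    return W - 1  # complete graph; unreachable for finite distances


def eigengap_k(
    graph: AffinityGraph,
    k_min: int = 2,
    k_max: int = 10,
    rule: str = "last-jump",
    jump_ratio: float = 1 / 3,
    require_connected: bool = True,
) -> tuple[int, np.ndarray]:
    """Cluster count from the eigengap of the unnormalized Laplacian.

    Returns (k, eigenvalues) with the eigenvalues ascending. The guiding
    principle is that for a graph with k loose communities the first k
    eigenvalues are all near zero and lambda_{k+1} is comparatively large.
    Rules:

    ``last-jump`` (default)
        k is the largest candidate with lambda_k <= jump_ratio *
        lambda_{k+1}, i.e. the last point at which the spectrum is still
        "small" relative to its successor. This reads the whole head of the
        spectrum and is robust when the between-community cut weights are
        heterogeneous (a single max-gap rule then latches onto the weakest
        cut) and to the roughly linear growth of the spectrum tail. Falls
        back to ``relative`` when no candidate jumps.
    ``relative``
        argmax of (lambda_{k+1} - lambda_k) / lambda_{k+1}.
    ``absolute``
        argmax of the plain difference lambda_{k+1} - lambda_k.

    The upper bound is clipped below half the number of windows. Set
    ``require_connected=False`` to inspect a deliberately disconnected toy
    (each component then contributes one zero eigenvalue).
    """
    W = len(graph)
    if require_connected and not is_connected(graph):
        raise ValueError(
            "affinity graph is disconnected; increase n (see min_connected_neighbors)"
        )
    k_max = int(min(k_max, np.ceil(W / 2) - 1))
    n_eigs = min(W, k_max + 1)
    vals, _ = _smallest_eigs(_laplacian(graph.w), n_eigs)
    lo, hi = k_min, min(k_max, len(vals) - 1)
    if lo > hi:
        raise ValueError(f"no admissible k in [{k_min}, {k_max}] for {W} windows")
    diffs = np.diff(vals)  # diffs[i-1] = lambda_{i+1} - lambda_i (1-indexed i)
    if rule == "last-jump":
        jumps = [
            i
            for i in range(lo, hi + 1)
            if vals[i - 1] <= jump_ratio * vals[i] + 1e-12
        ]
        if jumps:
            return int(jumps[-1]), vals
        rule = "relative"  # no clear jump: fall back to the max relative gap
    if rule == "relative":
        gaps = diffs / np.maximum(vals[1:], 1e-12)
    elif rule == "absolute":
        gaps = diffs
    else:
        raise ValueError(f"unknown eigengap rule {rule!r}")
    k = int(lo + np.argmax(gaps[lo - 1 : hi]))
    return k, vals


def spectral_partition(
    graph: AffinityGraph,
    k: int,
    seed: int = 0,
    n_init: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition the first-k eigenvector rows with seeded k-means.

    Returns (labels, embedding, centroids). Deterministic for a given seed.
    """
    W = len(graph)
    if not (2 <= k < W / 2):
        raise ValueError(f"k={k} outside the admissible range [2, {W / 2})")
    _, vecs = _smallest_eigs(_laplacian(graph.w), k, need_vectors=True)
    embedding = np.ascontiguousarray(vecs)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(embedding)
    return labels, embedding, km.cluster_centers_


def order_by_severity(
    labels: np.ndarray,
    windows: Sequence[GlucoseWindow],
) -> dict[int, str]:
    """Rank clusters by mean raw glucose of their member windows.

    Ascending rank maps onto low / moderate / severe for k = 3; any other k
    gets generic ordinal names class_1 (lowest) ... class_k.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    means = {}
    for c in clusters:
        member = [windows[i].raw_values.mean() for i in np.flatnonzero(labels == c)]
        means[int(c)] = float(np.mean(member))
    ranked = sorted(means, key=means.get)
    if len(ranked) == len(SEVERITY_ORDER):
        names = SEVERITY_ORDER
    else:
        names = tuple(f"class_{i + 1}" for i in range(len(ranked)))
    return {c: names[rank] for rank, c in enumerate(ranked)}


def cluster_mean_glucose(labels: np.ndarray, windows: Sequence[GlucoseWindow]) -> dict[int, float]:
    """Mean raw glucose (mg/dL) of the windows in each cluster."""
    labels = np.asarray(labels)
    return {
        int(c): float(
            np.mean(np.concatenate([windows[i].raw_values for i in np.flatnonzero(labels == c)]))
        )
        for c in np.unique(labels)
    }
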