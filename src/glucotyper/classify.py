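"""Out-of-sample classification of CGM windows into glycemic-signature classes.

New windows are scaled with the global training mean/sd, their CID-DTW
distances to a density-sampled reference subset of the training windows are
turned into affinities with a locally adaptive Gaussian kernel (the
similarity-network-fusion construction), the affinities project each new
window into the trained eigenvector space, and the class of the nearest
centroid is assigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import gaussian_kde

from glucotyper.cluster import ClusterModel, SEVERITY_ORDER
from glucotyper.distance import DissimilarityMatrix, pairwise_cross
from glucotyper.preprocess import GlucoseWindow

logger = logging.getLogger(__name__)

MIN_REFERENCES = 200
UNCLASSIFIABLE = "unclassifiable"


@dataclass
class ReferenceSet:
    """Density-sampled labeled subset of the training windows."""

    indices: np.ndarray  # positions in the model's training pool
    selection_seed: int

    @property
    def size(self) -> int:
        return int(self.indices.size)


def _knn_row_means(d: np.ndarray, k: int, axis: int = 1) -> np.ndarray:
    """Mean of the k smallest entries along ``axis`` (k clipped to the size)."""
    if axis == 0:
        d = d.T
    k = min(k, d.shape[1])
    part = np.partition(d, k - 1, axis=1)[:, :k]
    return part.mean(axis=1)


def snf_epsilon(d: np.ndarray, row_knn: np.ndarray, col_knn: np.ndarray) -> np.ndarray:
    """Locally adaptive kernel scale: (mean_kNN(i) + mean_kNN(j) + d_ij) / 3."""
    return (row_knn[:, None] + col_knn[None, :] + d) / 3.0


def estimate_sigma(D: DissimilarityMatrix | np.ndarray, k: int = 20) -> float:
    """Kernel scale making the median off-diagonal training affinity 0.5.

    With w = exp(-d^2 / (sigma * eps)), sigma = median(d^2 / eps) / ln 2 over
    all unordered training pairs.
    """
    d = D.d if isinstance(D, DissimilarityMatrix) else np.asarray(D, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need >= 2 training windows to estimate sigma")
    off = ~np.eye(n, dtype=bool)
    # kNN means exclude the self-distance
    knn = np.array(
        [np.partition(d[i][off[i]], min(k, n - 1) - 1)[: min(k, n - 1)].mean() for i in range(n)]
    )
    eps = snf_epsilon(d, knn, knn)
    iu = np.triu_indices(n, 1)
    ratio = d[iu] ** 2 / np.maximum(eps[iu], 1e-300)
    sigma = float(np.median(ratio) / np.log(2.0))
    if sigma <= 0:
        raise ValueError("degenerate training distances: sigma <= 0")
    return sigma


def select_references(
    model: ClusterModel,
    n_to_classify: int,
    seed: int = 0,
    min_references: int = MIN_REFERENCES,
) -> ReferenceSet:
    """Sample reference training windows, stratified per class.

    The target size is max(min_references, n_to_classify), capped at the
    training pool. Within each class, sampling probability is proportional to
    the Gaussian kernel density (Scott bandwidth) of the training points in
    eigenvector space, concentrating references around the class centroids;
    a class whose embedding is too degenerate for a KDE falls back to uniform
    weights. Deterministic for a given seed.
    """
    pool = len(model.ids)
    size = max(min_references, n_to_classify)
    if size >= pool:
        if size > pool:
            logger.warning(
                "select_references: requested %d references but pool has %d; using all",
                size,
                pool,
            )
        return ReferenceSet(indices=np.arange(pool), selection_seed=seed)
    rng = np.random.default_rng(seed)
    labels = np.asarray(model.labels)
    clusters = np.unique(labels)
    # proportional allocation, largest-remainder rounding
    counts = np.array([np.sum(labels == c) for c in clusters], dtype=float)
    quota = size * counts / counts.sum()
    alloc = np.floor(quota).astype(int)
    rem = size - alloc.sum()
    order = np.argsort(-(quota - alloc))
    alloc[order[:rem]] += 1
    alloc = np.minimum(alloc, counts.astype(int))
    chosen: list[np.ndarray] = []
    for c, n_c in zip(clusters, alloc):
        members = np.flatnonzero(labels == c)
        if n_c >= members.size:
            chosen.append(members)
            continue
        pts = model.embedding[members].T
        try:
            dens = gaussian_kde(pts)(pts)
            if not np.all(np.isfinite(dens)) or dens.sum() <= 0:
                raise np.linalg.LinAlgError
            p = dens / dens.sum()
        except np.linalg.LinAlgError:
            p = np.full(members.size, 1.0 / members.size)
        chosen.append(rng.choice(members, size=n_c, replace=False, p=p))
    indices = np.sort(np.concatenate(chosen))
    return ReferenceSet(indices=indices, selection_seed=seed)


def scale_new(values: Sequence[float], model: ClusterModel) -> np.ndarray:
    """Scale a raw mg/dL window with the stored training mean and sd."""
    v = np.asarray(values, dtype=float)
    if not model.windows:
        raise ValueError("model carries no training windows")
    m = len(model.windows[0])
    if v.size != m:
        raise ValueError(f"window length {v.size} != training length {m}")
    return (v - model.train_mean) / model.train_sd


def affinity_to_references(
    d_cross: np.ndarray,
    sigma: float,
    knn: int = 20,
) -> np.ndarray:
    """SNF-style affinity w_ij = exp(-d_ij^2 / (sigma * eps_ij)).

    eps_ij averages the mean k-nearest distance of new window i (across
    references), of reference j (across new windows), and d_ij itself.
    """
    if sigma <= 0:
        raise ValueError("model sigma must be positive")
    d = np.asarray(d_cross, dtype=float)
    row_knn = _knn_row_means(d, knn, axis=1)
    col_knn = _knn_row_means(d, knn, axis=0)
    eps = np.maximum(snf_epsilon(d, row_knn, col_knn), 1e-300)
    return np.exp(-(d**2) / (sigma * eps))


def _severity_rank(name: str) -> int:
    if name in SEVERITY_ORDER:
        return SEVERITY_ORDER.index(name)
    return int(name.rsplit("_", 1)[-1]) if "_" in name else 0


def project_and_assign(
    affinities: np.ndarray,
    refs: ReferenceSet,
    model: ClusterModel,
) -> list[str]:
    """Project new windows into eigenvector space and assign nearest centroid.

    Each new window's embedding is the affinity-weighted average of the
    reference windows' eigenvector rows, normalized to unit length; the label
    is the class of the nearest (Euclidean) centroid, ties broken toward the
    more severe class. All-zero affinity rows are marked unclassifiable.
    """
    A = np.asarray(affinities, dtype=float)
    ref_embed = model.embedding[refs.indices]
    row_sums = A.sum(axis=1)
    centroids = model.centroids
    c_norm = centroids / np.maximum(np.linalg.norm(centroids, axis=1, keepdims=True), 1e-300)
    severity = np.array([_severity_rank(model.class_of(c)) for c in range(model.k)])
    labels: list[str] = []
    for i in range(A.shape[0]):
        if row_sums[i] <= 0:
            labels.append(UNCLASSIFIABLE)
            continue
        z = A[i] @ ref_embed / row_sums[i]
        nz = np.linalg.norm(z)
        if nz == 0:
            labels.append(UNCLASSIFIABLE)
            continue
        z = z / nz
        dist = np.linalg.norm(c_norm - z, axis=1)
        best = np.flatnonzero(np.isclose(dist, dist.min()))
        c = best[np.argmax(severity[best])]
        labels.append(model.class_of(int(c)))
    return labels


def classify_windows(
    new_windows: Sequence[GlucoseWindow],
    model: ClusterModel,
    seed: int = 0,
    knn: int = 20,
) -> list[str]:
    """Classify new windows end to end (scale, distance, affinity, project).

    Both the new windows and the reference windows are represented in the
    training scale (global mean/sd) so their CID-DTW distances live in one
    space. Deterministic given (model, seed).
    """
    refs = select_references(model, len(new_windows), seed=seed)
    new_mat = np.vstack([scale_new(w.raw_values, model) for w in new_windows])
    ref_mat = np.vstack(
        [scale_new(model.windows[i].raw_values, model) for i in refs.indices]
    )
    d_cross = pairwise_cross(new_mat, ref_mat, metric="cid_dtw", band_fraction=model.band_fraction)
    A = affinity_to_references(d_cross, model.sigma, knn=knn)
    return project_and_assign(A, refs, model)
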