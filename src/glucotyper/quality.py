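"""Cluster-quality metrics and the window-size/overlap/metric optimization grid.

The sums of squares are distance-based: for any cluster C,
SS(C) = sum_{i<j in C} d_ij^2 / |C|, which reduces to the usual Euclidean
within-cluster sum of squared deviations when d is Euclidean. totSS is the
same quantity over all windows, totBSS = totSS - totWSS, and the proportion
of variance explained is totBSS / totSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from glucotyper.cgm_io import CGMSeries
from glucotyper.distance import DissimilarityMatrix, pairwise
from glucotyper.preprocess import WindowingConfig, preprocess_series


@dataclass
class QualityReport:
    """Clustering-quality summary for one partition of one distance matrix.

    entropy is in nats; silhouette / CH / Dunn are NaN markers when the
    partition has a single cluster.
    """

    n_clusters: int
    variance_explained: float
    silhouette_mean: float
    ch_index: float
    entropy: float
    dunn: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n_clusters": self.n_clusters,
            "variance_explained": self.variance_explained,
            "silhouette": self.silhouette_mean,
            "CH_index": self.ch_index,
            "entropy": self.entropy,
            "dunn": self.dunn,
        }


def _pooled_ss(d2: np.ndarray, idx: np.ndarray) -> float:
    """Sum over unordered pairs within idx of d^2, divided by |idx|."""
    if idx.size < 2:
        return 0.0
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / 2.0 / idx.size)


def sums_of_squares(D: DissimilarityMatrix, labels: np.ndarray) -> tuple[float, float, float]:
    """(totSS, totWSS, totBSS) from the pairwise-squared-distance decomposition."""
    labels = np.asarray(labels)
    d2 = D.d**2
    tot_ss = _pooled_ss(d2, np.arange(len(D)))
    tot_wss = sum(_pooled_ss(d2, np.flatnonzero(labels == c)) for c in np.unique(labels))
    return tot_ss, tot_wss, tot_ss - tot_wss


def cluster_quality(D: DissimilarityMatrix, labels: Sequence[int]) -> QualityReport:
    """Compute the full quality-metric suite for a labeled distance matrix.

    variance explained = totBSS / totSS; silhouette is the mean per-window
    silhouette on the precomputed distances (singletons score 0); CH =
    (totBSS / (k-1)) / (totWSS / (W-k)); entropy = -sum p_i log p_i (natural
    log) of the cluster-size fractions; Dunn = min inter-cluster distance /
    max cluster diameter.
    """
    labels = np.asarray(labels)
    W = len(D)
    if labels.size != W:
        raise ValueError("labels do not cover the matrix")
    clusters = np.unique(labels)
    k = clusters.size
    tot_ss, tot_wss, tot_bss = sums_of_squares(D, labels)
    sizes = np.array([np.sum(labels == c) for c in clusters], dtype=float)
    p = sizes / W
    entropy = float(-(p * np.log(p)).sum())
    if k == 1:
        return QualityReport(1, 0.0, np.nan, np.nan, entropy, np.nan)

    variance_explained = tot_bss / tot_ss if tot_ss > 0 else 0.0
    if k == W:  # all singletons: each scores 0 by convention
        sil = 0.0
    else:
        sil = float(silhouette_score(D.d, labels, metric="precomputed"))
    if tot_wss > 0 and k < W:
        ch = (tot_bss / (k - 1)) / (tot_wss / (W - k))
    else:
        ch = np.inf
    # Dunn: min between-cluster pairwise distance over max within diameter
    min_between = np.inf
    max_diam = 0.0
    for a_i, ca in enumerate(clusters):
        ia = np.flatnonzero(labels == ca)
        sub = D.d[np.ix_(ia, ia)]
        if ia.size > 1:
            max_diam = max(max_diam, float(sub.max()))
        for cb in clusters[a_i + 1 :]:
            ib = np.flatnonzero(labels == cb)
            min_between = min(min_between, float(D.d[np.ix_(ia, ib)].min()))
    dunn = min_between / max_diam if max_diam > 0 else np.inf
    return QualityReport(k, float(variance_explained), sil, float(ch), entropy, float(dunn))


def optimize_parameters(
    series_list: Sequence[CGMSeries],
    window_hours: Sequence[float] = (2.0, 2.5, 3.0),
    overlaps: Sequence[float] = (0.5, 0.75),
    metrics: Sequence[str] = ("euclidean", "dtw", "cid", "cid_dtw"),
    band_fraction: float = 0.10,
    seed: int = 0,
    k_min: int = 2,
    k_max: int = 10,
) -> pd.DataFrame:
    """Clustering-quality grid over (window size, overlap, distance metric).

    For each combination the cohort is re-windowed, the dissimilarity matrix
    rebuilt, the optimal k chosen by the eigengap heuristic, and the quality
    suite computed at that k. Returns a long-format table with columns
    distance, shift, window_size_hrs, clust_metric, value,
    window_overlap_perc; infeasible combinations are flagged with NaN values.
    """
    from glucotyper.cluster import (
        eigengap_k,
        knn_affinity,
        min_connected_neighbors,
        spectral_partition,
    )

    rows = []

    def emit(distance, shift, wh, overlap, report: dict):
        for metric_name, value in report.items():
            rows.append(
                {
                    "distance": distance,
                    "shift": shift,
                    "window_size_hrs": wh,
                    "clust_metric": metric_name,
                    "value": value,
                    "window_overlap_perc": int(round(overlap * 100)),
                }
            )

    for wh in window_hours:
        for overlap in overlaps:
            config = WindowingConfig(window_hours=wh, overlap_fraction=overlap)
            shift = config.nominal_shift_minutes
            try:
                windows = preprocess_series(series_list, config)
            except ValueError:
                windows = []
            for metric in metrics:
                if len(windows) < 6:
                    emit(metric, shift, wh, overlap, {"n_clusters": np.nan})
                    continue
                D = pairwise(windows, metric=metric, band_fraction=band_fraction)
                n = min_connected_neighbors(D)
                graph = knn_affinity(D, n)
                k, _ = eigengap_k(graph, k_min=k_min, k_max=k_max)
                labels, _, _ = spectral_partition(graph, k, seed=seed)
                emit(metric, shift, wh, overlap, cluster_quality(D, labels).as_dict())
    return pd.DataFrame(rows)
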