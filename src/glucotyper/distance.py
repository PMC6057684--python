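"""Banded DTW, complexity-invariant correction, and pairwise dissimilarity.

The warping distance uses the classical symmetric step pattern (diagonal
steps doubly weighted, |a - b| local cost) restricted to a Sakoe-Chiba band
of 10% of the window length by default. The complexity-invariant correction
multiplies the DTW value by the ratio of the two windows' first-difference
energies, penalizing pairs with mismatched waveform complexity. Distances are
always computed on z-scored windows, never raw mg/dL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from glucotyper.preprocess import GlucoseWindow

EPS_CE = 1e-12  # guard for flat windows in the complexity ratio

_METRIC_CODES = {"euclidean": 0, "dtw": 1, "cid": 2, "cid_dtw": 3}


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise distances between windows (unitless, z-scored)."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not match {n} ids")

    def __len__(self) -> int:
        return len(self.ids)


@njit(cache=True)
def _dtw_band(a, b, band, diag_weight):
    n = a.size
    m = b.size
    D = np.full((n, m), np.inf)
    for i in range(n):
        lo = i - band
        if lo < 0:
            lo = 0
        hi = i + band
        if hi > m - 1:
            hi = m - 1
        for j in range(lo, hi + 1):
            c = abs(a[i] - b[j])
            if i == 0 and j == 0:
                D[i, j] = c
                continue
            best = np.inf
            if i > 0 and j > 0 and D[i - 1, j - 1] < np.inf:
                best = D[i - 1, j - 1] + diag_weight * c
            if i > 0 and D[i - 1, j] < np.inf and D[i - 1, j] + c < best:
                best = D[i - 1, j] + c
            if j > 0 and D[i, j - 1] < np.inf and D[i, j - 1] + c < best:
                best = D[i, j - 1] + c
            D[i, j] = best
    return D[n - 1, m - 1]


@njit(cache=True)
def _ce(x):
    s = 0.0
    for i in range(x.size - 1):
        d = x[i + 1] - x[i]
        s += d * d
    return np.sqrt(s)


@njit(cache=True)
def _cid_factor(ce_a, ce_b, eps):
    hi = max(ce_a, ce_b)
    lo = min(ce_a, ce_b)
    if hi <= eps:
        return 1.0
    return hi / max(lo, eps)


@njit(cache=True)
def _pairwise_kernel(X, band, diag_weight, metric_code):
    n = X.shape[0]
    out = np.zeros((n, n))
    ce = np.empty(n)
    for i in range(n):
        ce[i] = _ce(X[i])
    for i in range(n):
        for j in range(i + 1, n):
            if metric_code == 0 or metric_code == 2:  # euclidean base
                s = 0.0
                for t in range(X.shape[1]):
                    d = X[i, t] - X[j, t]
                    s += d * d
                base = np.sqrt(s)
            else:
                base = _dtw_band(X[i], X[j], band, diag_weight)
            if metric_code >= 2:
                base *= _cid_factor(ce[i], ce[j], EPS_CE)
            out[i, j] = base
            out[j, i] = base
    return out


@njit(cache=True)
def _cross_kernel(X, Y, band, diag_weight, metric_code):
    n = X.shape[0]
    m = Y.shape[0]
    out = np.empty((n, m))
    ce_x = np.empty(n)
    ce_y = np.empty(m)
    for i in range(n):
        ce_x[i] = _ce(X[i])
    for j in range(m):
        ce_y[j] = _ce(Y[j])
    for i in range(n):
        for j in range(m):
            if metric_code == 0 or metric_code == 2:
                s = 0.0
                for t in range(X.shape[1]):
                    d = X[i, t] - Y[j, t]
                    s += d * d
                base = np.sqrt(s)
            else:
                base = _dtw_band(X[i], Y[j], band, diag_weight)
            if metric_code >= 2:
                base *= _cid_factor(ce_x[i], ce_y[j], EPS_CE)
            out[i, j] = base
    return out


def _band_width(length: int, band_fraction: float) -> int:
    if not (0 < band_fraction <= 1):
        raise ValueError("band_fraction must be in (0, 1]")
    return int(np.ceil(band_fraction * length))


def dtw(
    a: Sequence[float],
    b: Sequence[float],
    band_fraction: float = 0.10,
    diag_weight: float = 2.0,
) -> float:
    """Banded DTW distance under the symmetric step pattern.

    Minimal cumulative |a_i - b_j| cost over monotone warping paths, diagonal
    steps weighted ``diag_weight`` (2 = classical symmetric pattern, 1 = unit
    weights), restricted to a Sakoe-Chiba band of ceil(band_fraction * length)
    cells either side of the diagonal.
    """
    a = np.ascontiguousarray(a, dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("dtw() requires complete vectors")
    band = _band_width(max(a.size, b.size), band_fraction)
    val = _dtw_band(a, b, band, diag_weight)
    if not np.isfinite(val):
        raise ValueError(
            f"band of {band} samples admits no warping path for lengths {a.size}x{b.size}"
        )
    return float(val)


def complexity_estimate(x: Sequence[float]) -> float:
    """Complexity estimate CE(x) = sqrt(sum of squared first differences)."""
    x = np.ascontiguousarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("complexity_estimate requires length >= 2")
    return float(_ce(x))


def cid_dtw(
    a: Sequence[float],
    b: Sequence[float],
    band_fraction: float = 0.10,
    diag_weight: float = 2.0,
) -> float:
    """Complexity-invariant DTW: dtw(a, b) * max(CE)/min(CE).

    The correction factor is >= 1, so cid_dtw >= dtw; two flat vectors
    (both CE below the guard) get factor 1.
    """
    base = dtw(a, b, band_fraction, diag_weight)
    cf = _cid_factor(complexity_estimate(a), complexity_estimate(b), EPS_CE)
    return float(base * cf)


def _window_matrix(windows: Sequence[GlucoseWindow]) -> np.ndarray:
    degenerate = [w.id for w in windows if w.degenerate]
    if degenerate:
        raise ValueError(
            f"{len(degenerate)} degenerate (flat) window(s) present, e.g. "
            f"{degenerate[0]!r}; exclude them upstream before computing distances"
        )
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError(f"windows have mixed lengths {sorted(lengths)}")
    return np.ascontiguousarray(np.vstack([w.norm_values for w in windows]))


def pairwise(
    windows: Sequence[GlucoseWindow],
    metric: str = "cid_dtw",
    band_fraction: float = 0.10,
    diag_weight: float = 2.0,
) -> DissimilarityMatrix:
    """Pairwise dissimilarity matrix over normalized windows.

    metric is one of euclidean, dtw, cid (complexity-corrected euclidean),
    cid_dtw. Each unordered pair is computed once; the result is exactly
    symmetric with a zero diagonal.
    """
    if metric not in _METRIC_CODES:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRIC_CODES)}")
    X = _window_matrix(windows)
    band = _band_width(X.shape[1], band_fraction)
    d = _pairwise_kernel(X, band, diag_weight, _METRIC_CODES[metric])
    return DissimilarityMatrix(ids=[w.id for w in windows], d=d)


def pairwise_cross(
    new_windows_norm: np.ndarray,
    ref_windows_norm: np.ndarray,
    metric: str = "cid_dtw",
    band_fraction: float = 0.10,
    diag_weight: float = 2.0,
) -> np.ndarray:
    """Rectangular distance matrix between new and reference window vectors."""
    if metric not in _METRIC_CODES:
        raise ValueError(f"unknown metric {metric!r}")
    X = np.ascontiguousarray(new_windows_norm, dtype=float)
    Y = np.ascontiguousarray(ref_windows_norm, dtype=float)
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"length mismatch: {X.shape[1]} vs {Y.shape[1]}")
    band = _band_width(X.shape[1], band_fraction)
    return _cross_kernel(X, Y, band, diag_weight, _METRIC_CODES[metric])
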