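"""Glycemic-variability metrics for CGM windows and whole traces.

Covers descriptive statistics (mean/min/max/sd/IQR/quantiles), rate-of-change
measures, distance traveled, coefficient of variation, threshold-crossing
counts, MAGE via the Baghurst turning-point algorithm, the J index, and the
mean of daily differences (MODD) anchored at 06:00.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from glucotyper.cgm_io import CGMSeries
from glucotyper.preprocess import GlucoseWindow, smooth


@dataclass
class VariabilityReport:
    """Named glycemic-variability metrics (mg/dL unless noted)."""

    mean: float
    min: float
    max: float
    sd: float
    iqr: float
    median: float
    q25: float
    q75: float
    mean_rate: float  # mg/dL per minute, mean |slope|
    max_rate: float  # mg/dL per minute
    distance_traveled: float
    cv: float  # fraction, sd / mean
    mage: float
    j_index: float  # unitless composite
    n_crossings_140: int
    n_crossings_200: int
    frac_below_80: float
    frac_above_130: float
    modd: float = np.nan  # defined for multi-day traces only

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def upward_crossings(values: np.ndarray, threshold: float) -> int:
    """Number of entries into the range above ``threshold`` (events, not samples)."""
    v = np.asarray(values, dtype=float)
    above = v > threshold
    return int(np.sum(~above[:-1] & above[1:]) + int(above[0]))


def basic_stats(values: Sequence[float], interval_min: float = 5.0) -> dict[str, float]:
    """Descriptive statistics on a uniform-grid trace.

    Rates are first differences divided by the sampling interval in minutes;
    ``mean_rate`` averages absolute differences; ``distance_traveled`` is the
    total absolute change. Threshold counts are upward crossings.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 samples")
    dv = np.abs(np.diff(v))
    sd = float(v.std(ddof=1))
    mean = float(v.mean())
    q25, med, q75 = (float(q) for q in np.percentile(v, [25, 50, 75]))
    return {
        "mean": mean,
        "min": float(v.min()),
        "max": float(v.max()),
        "sd": sd,
        "iqr": q75 - q25,
        "median": med,
        "q25": q25,
        "q75": q75,
        "mean_rate": float(dv.mean() / interval_min),
        "max_rate": float(dv.max() / interval_min),
        "distance_traveled": float(dv.sum()),
        "cv": sd / mean if mean != 0 else np.nan,
        "n_crossings_140": upward_crossings(v, 140.0),
        "n_crossings_200": upward_crossings(v, 200.0),
        "frac_below_80": float(np.mean(v < 80.0)),
        "frac_above_130": float(np.mean(v > 130.0)),
    }


def _turning_points(s: np.ndarray) -> list[int]:
    """Indices of direction changes of s, plateau-compressed, with endpoints."""
    d = np.diff(s)
    nz = np.flatnonzero(d != 0)
    if nz.size == 0:
        return [0, s.size - 1]
    signs = np.sign(d[nz])
    tps = [0]
    for t in range(1, nz.size):
        if signs[t] != signs[t - 1]:
            tps.append(int(nz[t - 1] + 1))  # last sample of the previous move
    last = s.size - 1
    if tps[-1] != last:
        tps.append(last)
    return tps


def _prune_turning_points(idx: list[int], v: np.ndarray, sd: float) -> list[int]:
    """Iteratively enforce strictly alternating extrema with excursions >= sd."""
    idx = list(idx)
    while len(idx) > 1:
        x = v[idx]
        d = np.diff(x)
        flat = np.flatnonzero(d == 0)
        if flat.size:
            del idx[int(flat[0]) + 1]
            continue
        s = np.sign(d)
        mono = np.flatnonzero(s[:-1] == s[1:])  # same-direction runs: drop middle
        if mono.size:
            del idx[int(mono[0]) + 1]
            continue
        small = [
            i
            for i in range(1, len(idx) - 1)
            if abs(d[i - 1]) < sd and abs(d[i]) < sd
        ]
        if small:
            i = min(small, key=lambda i: max(abs(d[i - 1]), abs(d[i])))
            del idx[i]
            continue
        if abs(d[0]) < sd:
            del idx[0]
            continue
        if abs(d[-1]) < sd:
            del idx[-1]
            continue
        break
    return idx


def mage(
    values: Sequence[float],
    smooth_window: int = 5,
    smooth_order: int = 3,
    direction: str = "both",
) -> float:
    """Mean amplitude of glycemic excursions (Baghurst autodetection).

    The trace is smoothed to locate turning points; turning points whose
    excursions on both sides fall below one sample standard deviation of the
    whole trace are iteratively deleted (re-merging same-direction runs)
    until the retained extrema strictly alternate peak/nadir. MAGE is the
    mean amplitude of the retained excursions, measured on the raw values.
    ``direction`` selects "both" (headline), "ascending", or "descending".
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return 0.0
    sd = v.std(ddof=1)
    if sd == 0:
        return 0.0
    s = smooth(v, smooth_window, smooth_order) if v.size >= smooth_window else v
    idx = _prune_turning_points(_turning_points(s), v, sd)
    if len(idx) < 2:
        return 0.0
    d = np.diff(v[idx])
    d = d[np.abs(d) >= sd]
    if direction == "ascending":
        d = d[d > 0]
    elif direction == "descending":
        d = d[d < 0]
    elif direction != "both":
        raise ValueError(f"unknown direction {direction!r}")
    if d.size == 0:
        return 0.0
    return float(np.abs(d).mean())


def j_index(mean: float, sd: float) -> float:
    """J index = 0.001 * (mean + sd)^2, mean and sd in mg/dL."""
    if mean <= 0:
        raise ValueError("mean glucose must be positive")
    return 0.001 * (mean + sd) ** 2


def modd(
    series: CGMSeries,
    anchor_hour: int = 6,
    tolerance_min: float = 15.0,
) -> float:
    """Mean of daily differences: |glucose at 06:00| between consecutive days.

    For each calendar day the sample nearest the anchor time (within
    +/- tolerance) is used; days without a usable anchor are skipped, and the
    result is NaN when fewer than two consecutive anchored days exist.
    """
    times = pd.DatetimeIndex(series.times)
    days = sorted(set(times.normalize()))
    anchors: dict[pd.Timestamp, float] = {}
    for day in days:
        target = day + pd.Timedelta(hours=anchor_hour)
        offsets = np.abs((times - target).total_seconds())
        i = int(np.argmin(offsets))
        if offsets[i] <= tolerance_min * 60:
            anchors[day] = series.glucose[i]
    diffs = [
        abs(anchors[day] - anchors[prev])
        for prev, day in zip(days[:-1], days[1:])
        if prev in anchors and day in anchors
    ]
    if not diffs:
        return float("nan")
    return float(np.mean(diffs))


def variability_report(
    values: Sequence[float],
    interval_min: float = 5.0,
    series: CGMSeries | None = None,
) -> VariabilityReport:
    """Full metric suite for one window or trace; MODD requires ``series``."""
    b = basic_stats(values, interval_min)
    return VariabilityReport(
        **b,
        mage=mage(values),
        j_index=j_index(b["mean"], b["sd"]),
        modd=modd(series) if series is not None else np.nan,
    )


def class_metric_table(
    windows: Sequence[GlucoseWindow],
    interval_min: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class mean of each variability metric plus Kruskal-Wallis rank tests.

    Windows must carry class labels. Returns (per-class means, test table
    with columns statistic / pvalue / classes_tested). Classes with fewer
    than two windows are excluded from the test and flagged in the second
    table's attrs.
    """
    labeled = [w for w in windows if w.label is not None]
    if not labeled:
        raise ValueError("no labeled windows")
    rows = []
    for w in labeled:
        row = variability_report(w.raw_values, interval_min).as_dict()
        row.pop("modd")
        row["label"] = w.label
        rows.append(row)
    df = pd.DataFrame(rows)
    counts = df["label"].value_counts()
    testable = [c for c in counts.index if counts[c] >= 2]
    if len(testable) < 2:
        raise ValueError("need >= 2 classes with >= 2 windows each")
    means = df.groupby("label").mean()
    tests = {}
    for metric in [c for c in df.columns if c != "label"]:
        groups = [df.loc[df["label"] == c, metric].to_numpy() for c in testable]
        if all(np.allclose(g, groups[0][0]) for g in groups):
            tests[metric] = {"statistic": 0.0, "pvalue": 1.0}
            continue
        stat, p = stats.kruskal(*groups)
        tests[metric] = {"statistic": float(stat), "pvalue": float(p)}
    test_df = pd.DataFrame(tests).T
    test_df.attrs["classes_tested"] = testable
    test_df.attrs["classes_excluded"] = [c for c in counts.index if counts[c] < 2]
    return means, test_df
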