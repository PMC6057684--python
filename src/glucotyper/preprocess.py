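"""Raw CGM series -> equal-count, smoothed, z-normalized fixed-duration windows.

Processing order: resample to the uniform 5-minute grid with linear imputation
of short gaps, segment into sliding 2.5-hour windows with 75% overlap, smooth
each complete window with a Savitzky-Golay filter, then z-score it. Windows
touching an unfilled gap are dropped; per-subject window counts are equalized
to the cohort minimum by taking each subject's earliest windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from glucotyper.cgm_io import CGMSeries, window_id

logger = logging.getLogger(__name__)


@dataclass
class WindowingConfig:
    """Windowing and smoothing parameters.

    window_hours
        Window duration; 2.5 h approximates the duration of a meal response.
    overlap_fraction
        Fractional overlap of consecutive windows, in [0, 1). The default 0.75
        implies a 37.5-min shift, which is off the 5-min sampling grid; starts
        are realized as round(i * shift / grid) * grid (alternating 40/35-min
        steps) unless ``shift_minutes`` pins a fixed on-grid shift.
    max_imputable_gap_min
        Gaps strictly shorter than this are linearly imputed; longer gaps stay
        missing and disqualify overlapping windows.
    """

    window_hours: float = 2.5
    overlap_fraction: float = 0.75
    sampling_interval_min: float = 5.0
    max_imputable_gap_min: float = 15.0
    smooth_window: int = 5
    smooth_order: int = 3
    shift_minutes: float | None = None  # explicit on-grid shift override

    def __post_init__(self) -> None:
        if self.window_hours <= 0:
            raise ValueError("window_hours must be positive")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")

    @property
    def samples_per_window(self) -> int:
        return int(round(self.window_hours * 60 / self.sampling_interval_min))

    @property
    def nominal_shift_minutes(self) -> float:
        if self.shift_minutes is not None:
            return float(self.shift_minutes)
        return self.window_hours * 60 * (1 - self.overlap_fraction)


@dataclass
class GlucoseWindow:
    """A fixed-duration CGM segment: raw mg/dL values plus a z-scored form.

    ``norm_values`` are computed from the (optionally smoothed) raw values
    with the sample (n-1) standard deviation; a zero-variance window is
    flagged degenerate and must be excluded before distance computation.
    """

    subject_id: str
    start_time: np.datetime64
    raw_values: np.ndarray
    window_hours: float = 2.5
    shift_minutes: float = 37.5
    label: str | None = None
    norm_values: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.raw_values = np.asarray(self.raw_values, dtype=float)
        if self.norm_values is None:
            self.norm_values, self.degenerate = znormalize(self.raw_values)
        else:
            self.norm_values = np.asarray(self.norm_values, dtype=float)

    @property
    def id(self) -> str:
        return window_id(self.subject_id, self.window_hours, self.shift_minutes, self.start_time)

    def __len__(self) -> int:
        return int(self.raw_values.size)


@dataclass
class GriddedSeries:
    """A CGM series resampled to the uniform grid; NaN marks unfilled gaps."""

    subject_id: str
    times: np.ndarray  # datetime64[ns] uniform grid
    values: np.ndarray  # float, NaN where missing
    imputed: np.ndarray  # bool, True where linearly interpolated
    interval_min: float = 5.0


def impute_gaps(
    series: CGMSeries,
    max_gap_min: float = 15.0,
    interval_min: float = 5.0,
) -> GriddedSeries:
    """Resample onto the uniform grid and linearly fill short interior gaps.

    Gaps strictly shorter than ``max_gap_min`` (the spacing between the two
    observed samples flanking the hole) are linearly interpolated and marked
    imputed; a gap of exactly ``max_gap_min`` or more stays NaN.
    """
    if len(series) < 2:
        raise ValueError(f"series {series.subject_id!r}: need >= 2 samples to impute")
    step = np.timedelta64(int(interval_min * 60), "s")
    t0, t1 = series.times[0], series.times[-1]
    n = int((t1 - t0) // step) + 1
    grid = t0 + np.arange(n) * step
    values = np.full(n, np.nan)
    # snap each observation to its nearest grid point (first wins)
    idx = np.rint((series.times - t0) / step).astype(int)
    keep = (idx >= 0) & (idx < n)
    for i, g in zip(idx[keep][::-1], series.glucose[keep][::-1]):
        values[i] = g  # reversed so earliest observation wins collisions
    observed = ~np.isnan(values)
    imputed = np.zeros(n, dtype=bool)
    obs_idx = np.flatnonzero(observed)
    for a, b in zip(obs_idx[:-1], obs_idx[1:]):
        if b - a <= 1:
            continue
        gap_min = (b - a) * interval_min
        if gap_min < max_gap_min:
            frac = (np.arange(a + 1, b) - a) / (b - a)
            values[a + 1 : b] = values[a] + frac * (values[b] - values[a])
            imputed[a + 1 : b] = True
    return GriddedSeries(series.subject_id, grid, values, imputed, interval_min)


def smooth(values: np.ndarray, window: int = 5, order: int = 3) -> np.ndarray:
    """Savitzky-Golay (local polynomial least-squares) smoothing.

    Preserves polynomials up to ``order`` exactly, so constants and linear
    ramps pass through unchanged while isolated spikes are attenuated.
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("smooth() requires a complete (gap-free) vector")
    if values.size < window:
        raise ValueError(f"vector of length {values.size} shorter than smoothing window {window}")
    return savgol_filter(values, window_length=window, polyorder=order)


def znormalize(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    """Z-score with the sample (n-1) sd; returns (normalized, degenerate_flag)."""
    raw = np.asarray(raw, dtype=float)
    mu = raw.mean()
    sd = raw.std(ddof=1) if raw.size > 1 else 0.0
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(raw), True
    return (raw - mu) / sd, False


def window_starts(n_samples: int, config: WindowingConfig) -> list[int]:
    """Grid indices at which windows start, realizing the configured shift.

    With the default 37.5-min nominal shift, cumulative starts are rounded to
    the grid independently (0, 40, 75, 115, 150, ... minutes), which keeps the
    average shift exact.
    """
    m = config.samples_per_window
    grid = config.sampling_interval_min
    shift = config.nominal_shift_minutes
    starts = []
    i = 0
    while True:
        s = int(np.floor(i * shift / grid + 0.5))  # round-half-up, platform stable
        if s + m > n_samples:
            break
        starts.append(s)
        i += 1
    return starts


def segment(gridded: GriddedSeries, config: WindowingConfig | None = None) -> list[GlucoseWindow]:
    """Cut a gridded series into sliding windows; smooth + z-score each.

    Windows containing any unfilled (NaN) sample are dropped. Imputed samples
    do not disqualify a window. A series shorter than one window yields an
    empty list.
    """
    config = config or WindowingConfig()
    m = config.samples_per_window
    n = gridded.values.size
    out: list[GlucoseWindow] = []
    shift = config.nominal_shift_minutes
    for s in window_starts(n, config):
        raw = gridded.values[s : s + m]
        if np.isnan(raw).any():
            continue
        smoothed = smooth(raw, config.smooth_window, config.smooth_order)
        norm, degenerate = znormalize(smoothed)
        out.append(
            GlucoseWindow(
                subject_id=gridded.subject_id,
                start_time=gridded.times[s],
                raw_values=raw.copy(),
                window_hours=config.window_hours,
                shift_minutes=shift,
                norm_values=norm,
                degenerate=degenerate,
            )
        )
    return out


def equalize_counts(
    windows_by_subject: Mapping[str, Sequence[GlucoseWindow]],
) -> list[GlucoseWindow]:
    """Trim every subject to the cohort-minimum window count N, earliest first.

    Subjects with zero windows are excluded (with a warning) and do not drag
    N to zero.
    """
    nonempty = {s: list(ws) for s, ws in windows_by_subject.items() if len(ws) > 0}
    dropped = set(windows_by_subject) - set(nonempty)
    for s in sorted(dropped):
        logger.warning("equalize_counts: subject %s has no windows; excluded", s)
    if not nonempty:
        raise ValueError("no subject has any window")
    n_min = min(len(ws) for ws in nonempty.values())
    out: list[GlucoseWindow] = []
    for s in sorted(nonempty):
        ws = sorted(nonempty[s], key=lambda w: w.start_time)
        out.extend(ws[:n_min])
    return out


def preprocess_series(
    series_list: Iterable[CGMSeries],
    config: WindowingConfig | None = None,
    equalize: bool = True,
) -> list[GlucoseWindow]:
    """Full preprocessing: impute, segment, drop degenerate, equalize counts."""
    config = config or WindowingConfig()
    by_subject: dict[str, list[GlucoseWindow]] = {}
    for series in series_list:
        gridded = impute_gaps(series, config.max_imputable_gap_min, config.sampling_interval_min)
        wins = [w for w in segment(gridded, config) if not w.degenerate]
        by_subject[series.subject_id] = wins
    if equalize:
        return equalize_counts(by_subject)
    return [w for s in sorted(by_subject) for w in by_subject[s]]
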