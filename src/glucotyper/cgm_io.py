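"""Readers and writers for tab-delimited CGM, clinical, and meal-annotation tables.

The CGM format carries one glucose reading per row with columns ``DisplayTime``
(the analysis clock), ``GlucoseValue`` (mg/dL), ``subjectId``, and optionally
``InternalTime`` (retained but unused). Clinical tables are free-column TSVs
keyed on subject id; meal annotations carry ``Meal``, ``userID``, ``time``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MEAL_TYPES = frozenset({"bread+peanut-butter", "protein bar", "cornflakes+milk"})

CGM_REQUIRED_COLUMNS = ("DisplayTime", "GlucoseValue", "subjectId")


class FormatError(ValueError):
    """Raised when an input table violates the expected layout."""


@dataclass
class CGMSeries:
    """One subject's timestamped interstitial glucose trace in mg/dL.

    Timestamps are timezone-naive, strictly increasing, and deduplicated
    (first reading wins on sensor re-transmission).
    """

    subject_id: str
    times: np.ndarray  # datetime64[ns], sorted, unique
    glucose: np.ndarray  # float64, mg/dL, finite and > 0
    nominal_interval: pd.Timedelta = field(
        default_factory=lambda: pd.Timedelta(minutes=5)
    )

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.times.size == 0:
            raise ValueError(f"series {self.subject_id!r} has no samples")
        if self.times.size != self.glucose.size:
            raise ValueError("times and glucose lengths differ")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class ClinicalRecord:
    """Per-subject clinical measurements; missing values are None, never 0."""

    subject_id: str
    age: float | None = None
    bmi: float | None = None
    hba1c: float | None = None
    fbg: float | None = None
    ogtt_2h: float | None = None
    sspg: float | None = None
    fasting_insulin: float | None = None
    extras: dict = field(default_factory=dict)


@dataclass
class MealEvent:
    """A standardized-meal consumption annotation."""

    subject_id: str
    meal_type: str
    timestamp: np.datetime64
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if self.meal_type not in MEAL_TYPES:
            raise ValueError(
                f"meal_type {self.meal_type!r} not in {sorted(MEAL_TYPES)}"
            )


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty file: {path}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"empty file: {path}")
    return df


def read_cgm(path: str | Path) -> list[CGMSeries]:
    """Read a tab-delimited CGM file into one :class:`CGMSeries` per subject.

    ``DisplayTime`` is the analysis clock. Rows with non-numeric or
    non-positive glucose are dropped (count logged); duplicate timestamps
    within a subject keep the first occurrence.
    """
    df = _read_tsv(path)
    for col in CGM_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"CGM file {path} is missing column {col!r}")
    glucose = pd.to_numeric(df["GlucoseValue"], errors="coerce")
    bad = glucose.isna() | (glucose <= 0) | ~np.isfinite(glucose.fillna(np.nan))
    if bad.any():
        logger.info("read_cgm(%s): dropped %d non-numeric/non-positive rows", path, int(bad.sum()))
    df = df.loc[~bad].copy()
    df["GlucoseValue"] = glucose[~bad]
    df["DisplayTime"] = pd.to_datetime(df["DisplayTime"])
    series: list[CGMSeries] = []
    for sid, grp in df.groupby("subjectId", sort=True):
        grp = grp.sort_values("DisplayTime", kind="mergesort")
        dup = grp["DisplayTime"].duplicated(keep="first")
        if dup.any():
            logger.info("read_cgm: subject %s: dropped %d duplicate timestamps", sid, int(dup.sum()))
            grp = grp.loc[~dup]
        series.append(
            CGMSeries(
                subject_id=str(sid),
                times=grp["DisplayTime"].to_numpy(dtype="datetime64[ns]"),
                glucose=grp["GlucoseValue"].to_numpy(dtype=float),
            )
        )
    return series


_CLINICAL_FIELDS = {
    "age": "age",
    "bmi": "bmi",
    "hba1c": "hba1c",
    "fbg": "fbg",
    "ogtt_2h": "ogtt_2h",
    "sspg": "sspg",
    "fasting_insulin": "fasting_insulin",
}


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read a free-column clinical TSV keyed on ``subject_id``.

    Known columns (case-insensitive: age, bmi, hba1c, fbg, ogtt_2h, sspg,
    fasting_insulin) map to record fields; unknown columns are preserved in
    ``extras``. Empty cells become None. Duplicate subject ids are an error.
    """
    df = _read_tsv(path)
    id_col = None
    for cand in ("subject_id", "subjectId", "userID"):
        if cand in df.columns:
            id_col = cand
            break
    if id_col is None:
        raise FormatError(f"clinical file {path} has no subject id column")
    if df[id_col].duplicated().any():
        dups = df[id_col][df[id_col].duplicated()].tolist()
        raise FormatError(f"duplicate subject id(s) in {path}: {dups}")
    records = []
    lower_map = {c.lower(): c for c in df.columns if c != id_col}
    for i, row in df.iterrows():
        kwargs: dict = {}
        extras: dict = {}
        for lc, col in lower_map.items():
            raw = row[col]
            if pd.isna(raw) or str(raw).strip() == "":
                val = None
            elif lc in _CLINICAL_FIELDS:
                try:
                    val = float(raw)
                except ValueError as exc:
                    raise FormatError(
                        f"malformed numeric {raw!r} in column {col!r}, row {i} of {path}"
                    ) from exc
                if not np.isfinite(val) or val <= 0:
                    raise FormatError(
                        f"non-finite/non-positive {col!r}={raw!r} in row {i} of {path}"
                    )
            else:
                val = raw
            if lc in _CLINICAL_FIELDS:
                kwargs[_CLINICAL_FIELDS[lc]] = val
            else:
                extras[col] = val
        records.append(ClinicalRecord(subject_id=str(row[id_col]), extras=extras, **kwargs))
    return records


def read_meals(path: str | Path) -> list[MealEvent]:
    """Read meal annotations (columns Meal, userID, time); one event per row.

    Replicate indices are assigned per (subject, meal type) in time order.
    Rows with an empty timestamp are dropped (unrecorded meals are excluded
    from response scoring).
    """
    df = _read_tsv(path)
    for col in ("Meal", "userID", "time"):
        if col not in df.columns:
            raise FormatError(f"meal file {path} is missing column {col!r}")
    df = df.loc[df["time"].notna() & (df["time"].astype(str).str.strip() != "")].copy()
    df["time"] = pd.to_datetime(df["time"])
    df = df.sort_values(["userID", "Meal", "time"], kind="mergesort")
    events = []
    for (sid, meal), grp in df.groupby(["userID", "Meal"], sort=True):
        for rep, (_, row) in enumerate(grp.iterrows()):
            events.append(
                MealEvent(
                    subject_id=str(sid),
                    meal_type=str(meal),
                    timestamp=np.datetime64(row["time"], "ns"),
                    replicate_index=rep,
                )
            )
    return events


def window_id(subject_id: str, window_hours: float, shift_minutes: float, start) -> str:
    """Build a window identifier: subject id + window size (h) + shift (min) + start time."""
    start = pd.Timestamp(start)
    return f"{subject_id}_{window_hours:g}_{shift_minutes:g}_{start.isoformat()}"


def write_windows(windows, path: str | Path) -> None:
    """Serialize labeled windows to TSV (one row per window, values comma-joined)."""
    from glucotyper.preprocess import GlucoseWindow  # local to avoid cycle

    path = Path(path)
    rows = []
    for w in windows:
        if not isinstance(w, GlucoseWindow):
            raise TypeError(f"expected GlucoseWindow, got {type(w)}")
        rows.append(
            {
                "window_id": w.id,
                "subject_id": w.subject_id,
                "start_time": pd.Timestamp(w.start_time).isoformat(),
                "window_hours": w.window_hours,
                "shift_minutes": w.shift_minutes,
                "raw_values": ",".join(repr(float(v)) for v in w.raw_values),
                "label": "" if w.label is None else w.label,
            }
        )
    cols = ["window_id", "subject_id", "start_time", "window_hours",
            "shift_minutes", "raw_values", "label"]
    try:
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"cannot write windows to {path}: {exc}") from exc


def read_windows(path: str | Path):
    """Read windows written by :func:`write_windows`; inverse up to float repr."""
    from glucotyper.preprocess import GlucoseWindow

    df = _read_tsv(path)
    out = []
    for _, row in df.iterrows():
        raw = np.array([float(v) for v in str(row["raw_values"]).split(",")])
        label = row.get("label")
        if pd.isna(label) or str(label) == "":
            label = None
        out.append(
            GlucoseWindow(
                subject_id=str(row["subject_id"]),
                start_time=np.datetime64(pd.Timestamp(row["start_time"]), "ns"),
                raw_values=raw,
                window_hours=float(row["window_hours"]),
                shift_minutes=float(row["shift_minutes"]),
                label=label,
            )
        )
    return out
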