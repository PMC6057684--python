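"""Subject-level summaries: glucotypes, ADA diagnosis, time in range, meals.

A subject's glucotype is the glycemic-signature class (low / moderate /
severe) holding the largest fraction of their labeled windows. ADA diagnostic
thresholds: diabetes at HbA1c >= 6.5%, fasting glucose >= 126 mg/dL, or 2-h
OGTT >= 200 mg/dL; prediabetes at HbA1c in (5.7, 6.5), fasting glucose
100-125 mg/dL, or 2-h OGTT 140-199 mg/dL. Time-in-range uses the prediabetic
(140, 200] and diabetic (200, inf) mg/dL glycemic bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from glucotyper.cgm_io import CGMSeries, ClinicalRecord, MealEvent
from glucotyper.cluster import SEVERITY_ORDER
from glucotyper.preprocess import GlucoseWindow

DIAGNOSES = ("normoglycemic", "prediabetic", "diabetic")

# net carbohydrate (total minus fiber) ordering of the standardized meals
MEAL_NET_CARB_ORDER = ("bread+peanut-butter", "protein bar", "cornflakes+milk")


@dataclass
class GlucotypeSummary:
    subject_id: str
    fractions: dict[str, float]
    glucotype: str
    frac_prediabetic_range: float = np.nan
    frac_diabetic_range: float = np.nan


@dataclass
class MealResponse:
    subject_id: str
    meal_type: str
    replicate_index: int
    label: str  # severity class or "unclassifiable"


def class_fractions(labels: Sequence[str]) -> dict[str, float]:
    """Fraction of a subject's windows in each class; sums to 1."""
    labels = [l for l in labels if l is not None]
    if not labels:
        raise ValueError("no labeled windows")
    n = len(labels)
    observed = {}
    for l in labels:
        observed[l] = observed.get(l, 0) + 1
    names = SEVERITY_ORDER if set(observed) <= set(SEVERITY_ORDER) else sorted(observed)
    return {name: observed.get(name, 0) / n for name in names}


def _severity_rank(name: str) -> int:
    return SEVERITY_ORDER.index(name) if name in SEVERITY_ORDER else -1


def assign_glucotype(fractions: Mapping[str, float]) -> str:
    """Argmax-fraction class; exact ties resolve toward the more severe class."""
    if not fractions:
        raise ValueError("empty fractions")
    best = max(fractions.values())
    tied = [c for c, f in fractions.items() if f == best]
    return max(tied, key=_severity_rank)


def ada_diagnosis(record: ClinicalRecord) -> str:
    """ADA category from HbA1c, fasting glucose, and 2-h OGTT glucose.

    Diabetic if any diabetes criterion is met, else prediabetic if any
    prediabetes criterion is met, else normoglycemic. Missing measurements
    are skipped; all three missing is an error.
    """
    hba1c, fbg, ogtt = record.hba1c, record.fbg, record.ogtt_2h
    if hba1c is None and fbg is None and ogtt is None:
        raise ValueError(f"subject {record.subject_id}: no diagnostic measurement available")
    if (
        (hba1c is not None and hba1c >= 6.5)
        or (fbg is not None and fbg >= 126)
        or (ogtt is not None and ogtt >= 200)
    ):
        return "diabetic"
    if (
        (hba1c is not None and 5.7 < hba1c < 6.5)
        or (fbg is not None and 100 <= fbg <= 125)
        or (ogtt is not None and 140 <= ogtt <= 199)
    ):
        return "prediabetic"
    return "normoglycemic"


def time_in_ranges(series: CGMSeries) -> tuple[float, float]:
    """Fractions of readings in the prediabetic (140, 200] and diabetic
    (200, inf) mg/dL glycemic ranges."""
    v = np.asarray(series.glucose, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no readings")
    pre = float(np.mean((v > 140) & (v <= 200)))
    dia = float(np.mean(v > 200))
    return pre, dia


def classify_meal_response(
    windows: Sequence[GlucoseWindow],
    meal: MealEvent,
    margin_min: float = 20.0,
) -> MealResponse:
    """Score a standardized meal by its overlapping windows' classes.

    Candidate windows start within +/- ``margin_min`` minutes of the
    annotated consumption time (inclusive endpoints); the response class is
    the most severe among them. No candidate -> unclassifiable.
    """
    t = pd.Timestamp(meal.timestamp)
    lo, hi = t - pd.Timedelta(minutes=margin_min), t + pd.Timedelta(minutes=margin_min)
    candidates = [
        w.label
        for w in windows
        if w.subject_id == meal.subject_id
        and w.label in SEVERITY_ORDER
        and lo <= pd.Timestamp(w.start_time) <= hi
    ]
    if not candidates:
        label = "unclassifiable"
    else:
        label = max(candidates, key=_severity_rank)
    return MealResponse(meal.subject_id, meal.meal_type, meal.replicate_index, label)


def meal_severity_association(
    responses: Sequence[MealResponse],
    meal_order: Sequence[str] = MEAL_NET_CARB_ORDER,
) -> tuple[pd.DataFrame, float, float, pd.DataFrame]:
    """Contingency of response class by meal + chi-squared test.

    Meals are ordered by net carbohydrate content. Returns (counts table,
    chi2 statistic, p-value, observed/expected ratio table). Any zero
    expected count is an error.
    """
    usable = [r for r in responses if r.label in SEVERITY_ORDER]
    if not usable:
        raise ValueError("no classifiable responses")
    df = pd.DataFrame({"meal": [r.meal_type for r in usable], "label": [r.label for r in usable]})
    meals = [m for m in meal_order if m in set(df["meal"])] + sorted(
        set(df["meal"]) - set(meal_order)
    )
    classes = [c for c in SEVERITY_ORDER if c in set(df["label"])]
    if len(meals) < 2 or len(classes) < 2:
        raise ValueError("need >= 2 meal types and >= 2 classes populated")
    table = pd.crosstab(df["meal"], df["label"]).reindex(index=meals, columns=classes)
    chi2, p, _, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    if np.any(expected == 0):
        raise ValueError("zero expected count in contingency table")
    ratio = pd.DataFrame(table.to_numpy() / expected, index=table.index, columns=table.columns)
    return table, float(chi2), float(p), ratio


def summarize_subject(
    subject_id: str,
    labels: Sequence[str],
    series: CGMSeries | None = None,
) -> GlucotypeSummary:
    """Class fractions + glucotype (+ time-in-range when the trace is given)."""
    fractions = class_fractions(labels)
    glucotype = assign_glucotype(fractions)
    if series is not None:
        pre, dia = time_in_ranges(series)
    else:
        pre = dia = np.nan
    return GlucotypeSummary(subject_id, fractions, glucotype, pre, dia)
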