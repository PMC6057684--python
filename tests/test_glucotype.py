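"""Subject summaries: class fractions, glucotype, ADA diagnosis, meals."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glucotyper as gt
from glucotyper.cgm_io import ClinicalRecord, MealEvent
from glucotyper.glucotype import (
    MealResponse,
    ada_diagnosis,
    assign_glucotype,
    class_fractions,
    classify_meal_response,
    meal_severity_association,
    time_in_ranges,
)
from glucotyper.preprocess import GlucoseWindow


class TestClassFractions:
    def test_all_low(self):
        f = class_fractions(["low"] * 5)
        assert f == {"low": 1.0, "moderate": 0.0, "severe": 0.0}

    def test_half_low_half_severe(self):
        f = class_fractions(["low"] * 119 + ["severe"] * 119)
        assert f["low"] == pytest.approx(0.5)
        assert f["moderate"] == 0.0
        assert f["severe"] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["low", "moderate", "severe"], size=238).tolist()
        assert sum(class_fractions(labels).values()) == pytest.approx(1.0, abs=1e-9)

    def test_no_windows_is_error(self):
        with pytest.raises(ValueError):
            class_fractions([])


class TestAssignGlucotype:
    def test_majority_class_wins(self):
        assert assign_glucotype({"low": 0.6, "moderate": 0.3, "severe": 0.1}) == "low"

    def test_tie_breaks_toward_more_severe(self):
        assert assign_glucotype({"low": 0.4, "moderate": 0.4, "severe": 0.2}) == "moderate"
        assert assign_glucotype({"low": 0.5, "moderate": 0.0, "severe": 0.5}) == "severe"

    def test_argmax_property(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.dirichlet([1, 1, 1])
            f = dict(zip(("low", "moderate", "severe"), p))
            g = assign_glucotype(f)
            assert f[g] == max(f.values())


def _record(hba1c=5.0, fbg=90.0, ogtt=120.0, **kw):
    return ClinicalRecord("X", hba1c=hba1c, fbg=fbg, ogtt_2h=ogtt, **kw)


class TestAdaDiagnosis:
    @pytest.mark.parametrize(
        "record, expected",
        [
            (_record(hba1c=6.5), "diabetic"),
            (_record(fbg=126), "diabetic"),
            (_record(ogtt=200), "diabetic"),
            (_record(fbg=100), "prediabetic"),
            (_record(fbg=125), "prediabetic"),
            (_record(ogtt=140), "prediabetic"),
            (_record(hba1c=5.8), "prediabetic"),
            (_record(hba1c=5.6, fbg=99, ogtt=139), "normoglycemic"),
            (_record(hba1c=5.7), "normoglycemic"),  # strictly > 5.7 for prediabetes
        ],
    )
    def test_threshold_table(self, record, expected):
        assert ada_diagnosis(record) == expected

    def test_missing_measures_skipped(self):
        rec = ClinicalRecord("X", fbg=130.0)
        assert ada_diagnosis(rec) == "diabetic"

    def test_all_missing_is_error(self):
        with pytest.raises(ValueError):
            ada_diagnosis(ClinicalRecord("X"))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.floats(4.0, 9.0),
        st.floats(70.0, 250.0),
        st.floats(80.0, 300.0),
        st.sampled_from(["hba1c", "fbg", "ogtt"]),
        st.floats(0.1, 2.0),
    )
    def test_monotone_in_every_measure(self, a1c, fbg, ogtt, which, bump):
        order = {"normoglycemic": 0, "prediabetic": 1, "diabetic": 2}
        base = _record(hba1c=a1c, fbg=fbg, ogtt=ogtt)
        raised = _record(
            hba1c=a1c + (bump if which == "hba1c" else 0),
            fbg=fbg + (bump * 10 if which == "fbg" else 0),
            ogtt=ogtt + (bump * 10 if which == "ogtt" else 0),
        )
        assert order[ada_diagnosis(raised)] >= order[ada_diagnosis(base)]


class TestTimeInRanges:
    def test_constant_normal(self):
        s = gt.CGMSeries("X", pd.date_range("2021-03-01", periods=10, freq="5min").to_numpy(),
                         np.full(10, 100.0))
        assert time_in_ranges(s) == (0.0, 0.0)

    def test_half_prediabetic(self):
        v = np.array([150.0] * 5 + [90.0] * 5)
        s = gt.CGMSeries("X", pd.date_range("2021-03-01", periods=10, freq="5min").to_numpy(), v)
        pre, dia = time_in_ranges(s)
        assert pre == pytest.approx(0.5)
        assert dia == 0.0

    def test_ranges_disjoint_and_complete(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(60, 260, size=200)
        s = gt.CGMSeries("X", pd.date_range("2021-03-01", periods=200, freq="5min").to_numpy(), v)
        pre, dia = time_in_ranges(s)
        normal = np.mean(v <= 140)
        assert pre + dia + normal == pytest.approx(1.0)
        assert np.mean(v == 200.0) == 0  # boundary: 200 counts as prediabetic
        s200 = gt.CGMSeries("X", s.times[:2], np.array([200.0, 201.0]))
        assert time_in_ranges(s200) == (0.5, 0.5)


def _labeled_window(label, sid="A", start="2021-03-02 07:30"):
    return GlucoseWindow(
        subject_id=sid,
        start_time=np.datetime64(pd.Timestamp(start), "ns"),
        raw_values=100 + np.arange(30.0),
        label=label,
    )


class TestMealResponse:
    def _meal(self, ts="2021-03-02 07:30", sid="A"):
        return MealEvent(sid, "protein bar", np.datetime64(pd.Timestamp(ts), "ns"))

    def test_uniform_candidates(self):
        ws = [_labeled_window("low", start="2021-03-02 07:20"),
              _labeled_window("low", start="2021-03-02 07:45")]
        assert classify_meal_response(ws, self._meal()).label == "low"

    def test_most_severe_candidate_wins(self):
        ws = [_labeled_window("low", start="2021-03-02 07:15"),
              _labeled_window("moderate", start="2021-03-02 07:30"),
              _labeled_window("severe", start="2021-03-02 07:50")]
        assert classify_meal_response(ws, self._meal()).label == "severe"

    def test_order_invariance(self):
        ws = [_labeled_window("moderate", start="2021-03-02 07:15"),
              _labeled_window("severe", start="2021-03-02 07:40")]
        a = classify_meal_response(ws, self._meal()).label
        b = classify_meal_response(list(reversed(ws)), self._meal()).label
        assert a == b == "severe"

    def test_windows_outside_40_min_interval_ignored(self):
        ws = [_labeled_window("severe", start="2021-03-02 06:30"),
              _labeled_window("low", start="2021-03-02 07:30")]
        assert classify_meal_response(ws, self._meal()).label == "low"

    def test_no_candidate_marked_unclassifiable(self):
        ws = [_labeled_window("severe", start="2021-03-02 10:00")]
        assert classify_meal_response(ws, self._meal()).label == "unclassifiable"

    def test_other_subjects_windows_excluded(self):
        ws = [_labeled_window("severe", sid="B")]
        assert classify_meal_response(ws, self._meal(sid="A")).label == "unclassifiable"


class TestMealAssociation:
    def test_chi2_matches_direct_formula(self):
        responses = (
            [MealResponse("s", "cornflakes+milk", 0, "severe")] * 12
            + [MealResponse("s", "cornflakes+milk", 0, "low")] * 3
            + [MealResponse("s", "protein bar", 0, "severe")] * 5
            + [MealResponse("s", "protein bar", 0, "low")] * 10
            + [MealResponse("s", "bread+peanut-butter", 0, "severe")] * 4
            + [MealResponse("s", "bread+peanut-butter", 0, "low")] * 11
        )
        table, chi2, p, ratio = meal_severity_association(responses)
        obs = table.to_numpy().astype(float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert chi2 == pytest.approx(((obs - expected) ** 2 / expected).sum())
        assert table.index[-1] == "cornflakes+milk"  # highest net carbohydrate

    def test_uniform_responses_give_p_near_one(self):
        responses = [
            MealResponse("s", meal, 0, label)
            for meal in ("protein bar", "cornflakes+milk")
            for label in ("low", "severe")
            for _ in range(10)
        ]
        _, _, p, _ = meal_severity_association(responses)
        assert p > 0.95

    def test_unclassifiable_responses_excluded(self):
        responses = [MealResponse("s", "protein bar", 0, "unclassifiable")] * 5
        with pytest.raises(ValueError):
            meal_severity_association(responses)
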