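"""Imputation, smoothing, normalization, segmentation, count equalization."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from glucotyper.cgm_io import CGMSeries
from glucotyper.preprocess import (
    WindowingConfig,
    equalize_counts,
    impute_gaps,
    segment,
    smooth,
    window_starts,
    znormalize,
)


def _series(minutes, values, sid="A"):
    t0 = np.datetime64("2021-03-01T00:00", "ns")
    times = t0 + np.array(minutes, dtype="timedelta64[m]").astype("timedelta64[ns]")
    return CGMSeries(subject_id=sid, times=times, glucose=np.asarray(values, float))


def _gapless(n_min, sid="A", seed=0):
    rng = np.random.default_rng(seed)
    mins = np.arange(0, n_min + 1, 5)
    return _series(mins, 100 + 5 * rng.normal(size=mins.size), sid)


class TestImputeGaps:
    def test_linear_midpoint_for_10_min_gap(self):
        s = _series([0, 10], [100, 110])
        g = impute_gaps(s)
        assert g.values.tolist() == [100, 105, 110]
        assert g.imputed.tolist() == [False, True, False]

    def test_20_min_gap_left_missing(self):
        s = _series([0, 20], [100, 120])
        g = impute_gaps(s)
        assert np.isnan(g.values[1:4]).all()

    def test_gap_of_exactly_15_min_not_imputed(self):
        # "under 15 minutes" is strict: a 15-min hole stays missing
        s = _series([0, 15], [100, 115])
        g = impute_gaps(s)
        assert np.isnan(g.values[1:3]).all()
        s2 = _series([0, 5, 20], [100, 105, 120])  # 15-min hole after sample 2
        g2 = impute_gaps(s2)
        assert np.isnan(g2.values[2]).all() if np.ndim(g2.values[2]) else np.isnan(g2.values[2])

    def test_10_min_gap_imputed_but_marked(self):
        s = _series([0, 5, 15, 20], [100, 105, 115, 120])
        g = impute_gaps(s)
        assert g.values[2] == pytest.approx(110)
        assert g.imputed[2]

    def test_single_sample_is_error(self):
        with pytest.raises(ValueError):
            impute_gaps(_series([0], [100]))


class TestSmooth:
    def test_constant_unchanged(self):
        x = np.full(20, 107.0)
        assert np.allclose(smooth(x), x)

    def test_linear_ramp_unchanged(self):
        x = np.linspace(80, 140, 30)
        assert np.allclose(smooth(x), x, atol=1e-9)

    def test_spike_attenuated_and_matches_local_lsq_oracle(self):
        x = np.zeros(15)
        x[7] = 10.0
        sm = smooth(x, window=5, order=3)
        assert sm[7] < 10.0
        # oracle: direct least-squares cubic fit on the centered 5-point stencil
        idx = np.arange(5, 10)
        coeffs = np.polyfit(idx - 7, x[idx], 3)
        assert sm[7] == pytest.approx(np.polyval(coeffs, 0))

    def test_too_short_vector_is_error(self):
        with pytest.raises(ValueError):
            smooth(np.arange(3.0), window=5)


class TestZNormalize:
    def test_printed_example(self):
        norm, degenerate = znormalize(np.array([90.0, 100.0, 110.0]))
        assert not degenerate
        assert np.allclose(norm, [-1, 0, 1])  # sample sd = 10

    def test_constant_window_degenerate(self):
        norm, degenerate = znormalize(np.full(30, 100.0))
        assert degenerate
        assert np.all(norm == 0)

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        norm, degenerate = znormalize(100 + 9 * rng.normal(size=30))
        assert not degenerate
        assert abs(norm.mean()) < 1e-9
        assert abs(norm.std(ddof=1) - 1) < 1e-9


class TestSegment:
    def test_series_shorter_than_window_yields_nothing(self):
        g = impute_gaps(_gapless(115))  # 2 h < 2.5 h window
        assert segment(g) == []

    def test_fixed_40_min_shift_start_times(self):
        # 5-h series, explicit 40-min shift: starts at 0, 40, 80, 120 min
        g = impute_gaps(_gapless(300))
        config = WindowingConfig(shift_minutes=40)
        ws = segment(g, config)
        starts = [(pd.Timestamp(w.start_time) - pd.Timestamp(g.times[0])).seconds // 60
                  for w in ws]
        assert starts == [0, 40, 80, 120]

    def test_enumeration_oracle_for_window_count(self):
        # count = number of grid starts with a full window inside the series
        for total_min, shift in [(300, 40), (600, 35), (450, 40)]:
            g = impute_gaps(_gapless(total_min))
            config = WindowingConfig(shift_minutes=shift)
            ws = segment(g, config)
            m = config.samples_per_window
            n = g.values.size
            expected = sum(
                1 for i in range(n) if i % (shift // 5) == 0 and i + m <= n
            )
            assert len(ws) == expected

    def test_default_shift_alternates_40_35_minutes(self):
        starts = window_starts(200, WindowingConfig())
        mins = [s * 5 for s in starts]
        shifts = np.diff(mins)
        assert mins[:5] == [0, 40, 75, 115, 150]
        assert set(shifts) == {35, 40}
        # average shift preserves the nominal 37.5-min (75%) overlap
        assert np.mean(shifts) == pytest.approx(37.5, abs=0.5)

    def test_windows_overlapping_long_gap_dropped(self):
        mins = list(range(0, 150, 5)) + list(range(170, 470, 5))
        vals = 100 + np.arange(len(mins)) % 7
        g = impute_gaps(_series(mins, vals))
        ws = segment(g, WindowingConfig(shift_minutes=40))
        for w in ws:
            assert not np.isnan(w.raw_values).any()
        gap_start = pd.Timestamp("2021-03-01 02:30")
        for w in ws:
            start = pd.Timestamp(w.start_time)
            end = start + pd.Timedelta(minutes=145)
            assert not (start <= gap_start <= end)

    def test_every_window_has_m_samples(self):
        g = impute_gaps(_gapless(1000))
        for w in segment(g):
            assert len(w) == 30

    def test_translation_by_one_shift_drops_first_window(self):
        config = WindowingConfig(shift_minutes=40)
        s = _gapless(600)
        ws_all = segment(impute_gaps(s), config)
        shifted = CGMSeries("A", s.times[8:], s.glucose[8:])  # drop 40 min
        ws_shift = segment(impute_gaps(shifted), config)
        assert len(ws_shift) == len(ws_all) - 1
        assert ws_shift[0].start_time == ws_all[1].start_time
        assert np.allclose(ws_shift[0].raw_values, ws_all[1].raw_values)


class TestEqualize:
    def _windows_for(self, sid, n):
        g = impute_gaps(_gapless(150 + 40 * (n - 1) + 5, sid=sid, seed=hashsid(sid)))
        ws = segment(g, WindowingConfig(shift_minutes=40))
        assert len(ws) >= n
        return ws[:n]

    def test_trim_to_minimum(self):
        by_subject = {
            "A": self._windows_for("A", 10),
            "B": self._windows_for("B", 12),
            "C": self._windows_for("C", 15),
        }
        out = equalize_counts(by_subject)
        counts = {s: sum(w.subject_id == s for w in out) for s in "ABC"}
        assert counts == {"A": 10, "B": 10, "C": 10}

    def test_single_subject_unchanged(self):
        ws = self._windows_for("A", 7)
        assert len(equalize_counts({"A": ws})) == 7

    def test_zero_window_subject_excluded(self):
        by_subject = {"A": self._windows_for("A", 5), "B": []}
        out = equalize_counts(by_subject)
        assert {w.subject_id for w in out} == {"A"}
        assert len(out) == 5

    def test_earliest_windows_kept(self):
        ws = self._windows_for("A", 9)
        out = equalize_counts({"A": ws[:9], "B": self._windows_for("B", 4)})
        kept = [w for w in out if w.subject_id == "A"]
        assert [w.start_time for w in kept] == [w.start_time for w in ws[:4]]


def hashsid(sid: str) -> int:
    return sum(ord(c) for c in sid)
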