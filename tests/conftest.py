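"""Shared fixtures: synthetic cohorts and trained models built once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import glucotyper as gt


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject, two-day cohort with two subjects per variability regime."""
    config = gt.SimulationConfig(n_subjects=6, days=2.0, seed=7)
    return gt.simulate_cohort(
        config, regimes=["low", "low", "moderate", "moderate", "severe", "severe"]
    )


@pytest.fixture(scope="session")
def small_model(small_cohort):
    """Spectral model trained on the small cohort (k pinned to 3)."""
    model, D = gt.fit_model(small_cohort["series"], seed=11, k=3)
    return model, D


@pytest.fixture()
def toy_series():
    """A gapless 1-day trace at exact 5-minute sampling."""
    times = pd.date_range("2021-03-01", periods=288, freq="5min").to_numpy()
    rng = np.random.default_rng(5)
    glucose = 100 + 20 * np.sin(np.arange(288) / 20) + rng.normal(0, 2, 288)
    return gt.CGMSeries(subject_id="T1", times=times, glucose=glucose)


def write_cgm_tsv(path, series_list):
    """Serialize CGMSeries to the tab-delimited ingest format."""
    rows = []
    for s in series_list:
        for t, g in zip(s.times, s.glucose):
            rows.append(
                {
                    "DisplayTime": pd.Timestamp(t).isoformat(),
                    "GlucoseValue": g,
                    "subjectId": s.subject_id,
                    "InternalTime": pd.Timestamp(t).isoformat(),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
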