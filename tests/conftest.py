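"""Shared fixtures: hand-built CGM days, a small synthetic cohort, and
a LibreView-export fixture generated on the fly."""

from __future__ import annotations

from datetime import date as Date

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import dawnprob as dp

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

DAY = Date(2023, 5, 10)


def make_day(points, date=DAY):
    """DayTrace from ('HH:MM', glucose) pairs on a fixed date."""
    idx = pd.DatetimeIndex(
        [pd.Timestamp(f"{date.isoformat()} {hhmm}") for hhmm, _ in points])
    return dp.DayTrace(date, pd.Series([v for _, v in points], index=idx))


@pytest.fixture
def day_factory():
    return make_day


@pytest.fixture
def rules():
    return dp.BreakfastRules()


@pytest.fixture
def toy_model():
    """Per-measurement likelihood scale at the Libre-Pro-derived sigma."""
    return dp.ErrorModel(dp.LIBRE_SIGMA, "single", gamma=20.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Noisy three-stratum cohort: 3 x 6 participants x 14 days."""
    spec = dp.default_cohort_spec(n_per_stratum=6, days=14, seed=11)
    return spec, dp.generate_cohort(spec)


@pytest.fixture
def libreview_file(tmp_path):
    lines = [
        "Glucose Data,Generated by LibreView,01-02-2023",
        "Patient Report,Example Patient",
        "Device,Serial Number,Device Timestamp,Record Type,"
        "Historic Glucose mg/dL,Scan Glucose mg/dL",
        "FreeStyle Libre Pro,ABC123,01-01-2023 00:15,0,101,",
        "FreeStyle Libre Pro,ABC123,01-01-2023 00:30,0,99,",
        "FreeStyle Libre Pro,ABC123,01-01-2023 00:42,1,,105",
        "FreeStyle Libre Pro,ABC123,01-01-2023 00:45,0,98,",
        "FreeStyle Libre Pro,ABC123,01-01-2023 01:00,0,97,",
        "FreeStyle Libre Pro,ABC123,01-01-2023 01:15,0,102,",
    ]
    p = tmp_path / "export.csv"
    p.write_text("\n".join(lines) + "\n")
    return p
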