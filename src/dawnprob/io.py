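"""Reading, validation and day-level segmentation of CGM traces.

Two input dialects are supported:

* a generic *long* CSV with one row per reading
  (``participant_id, timestamp, glucose_mgdl``), and
* the LibreView export produced for FreeStyle Libre Pro readers: a short
  metadata preamble, then a header row containing a device-timestamp
  column and a *historic* glucose column in mg/dL.  Only historic
  (record type 0) rows are retained; scan rows are discarded.

All glucose values are handled in mg/dL.  Files whose glucose column is
labelled in mmol/L are rejected rather than converted: the downstream
thresholds (20, 40, 70, 140 mg/dL) are unit-bound and a silent 18-fold
conversion error would be catastrophic.

Days are delimited at local-clock midnight with the half-open convention
[00:00, 24:00): a sample stamped exactly 00:00 belongs to the *new* day.
No time-zone conversion is performed; CGM exports carry wall-clock time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "UnitError",
    "CGMTrace",
    "DayTrace",
    "WearCheck",
    "read_long_csv",
    "read_libreview_csv",
    "write_long_csv",
    "split_days",
    "passes_wear_requirement",
    "infer_sampling_interval_min",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """The input file does not match the expected dialect."""


class UnitError(FormatError):
    """The glucose column is not in mg/dL (mmol/L inputs are rejected)."""


def _as_sample_series(timestamps, glucose) -> pd.Series:
    """Build a validated glucose series indexed by timestamp.

    Sorts by time, drops duplicate timestamps keeping the first
    occurrence (with a warning), and checks positivity/finiteness.
    """
    idx = pd.DatetimeIndex(pd.to_datetime(timestamps))
    s = pd.Series(np.asarray(glucose, dtype=float), index=idx)
    s = s.sort_index(kind="stable")
    if s.index.has_duplicates:
        n_dup = int(s.index.duplicated(keep="first").sum())
        logger.warning("dropping %d duplicate-timestamp samples (keeping first)", n_dup)
        s = s[~s.index.duplicated(keep="first")]
    vals = s.to_numpy()
    if len(vals) and (not np.all(np.isfinite(vals)) or np.any(vals <= 0)):
        raise ValueError("glucose samples must be positive and finite")
    return s


@dataclass
class CGMTrace:
    """One participant's CGM record.

    ``samples`` is a float glucose series (mg/dL) indexed by a strictly
    increasing :class:`pandas.DatetimeIndex` of local-clock timestamps.
    """

    participant_id: str
    samples: pd.Series
    device: str = "unknown"

    def __post_init__(self) -> None:
        if not isinstance(self.samples.index, pd.DatetimeIndex):
            raise TypeError("samples must be indexed by timestamps")
        if not self.samples.index.is_monotonic_increasing or self.samples.index.has_duplicates:
            raise ValueError("samples must be strictly increasing in time; "
                             "use CGMTrace.from_samples to sort/deduplicate")

    @classmethod
    def from_samples(cls, participant_id: str, timestamps, glucose,
                     device: str = "unknown") -> "CGMTrace":
        """Construct a trace, sorting and deduplicating deterministically."""
        return cls(participant_id, _as_sample_series(timestamps, glucose), device)

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class DayTrace:
    """All samples of one calendar day, [00:00, 24:00) local clock."""

    date: Date
    samples: pd.Series

    def __post_init__(self) -> None:
        if len(self.samples) and not (self.samples.index.normalize() == pd.Timestamp(self.date)).all():
            raise ValueError("DayTrace samples must all fall on its date")

    def __len__(self) -> int:
        return len(self.samples)


def read_long_csv(path, *, id_col: str = "participant_id", time_col: str = "timestamp",
                  glucose_col: str = "glucose_mgdl", device: str = "unknown",
                  max_bad_fraction: float = 0.10) -> list[CGMTrace]:
    """Read a generic long-format CGM CSV into one trace per participant.

    Malformed rows (unparseable timestamps, non-numeric or non-positive
    glucose) are counted and logged; the read aborts with
    :class:`FormatError` if more than ``max_bad_fraction`` of rows fail.

    Returns traces sorted by participant id, each with time-sorted,
    deduplicated samples.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in (id_col, time_col, glucose_col) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")
    if df.empty:
        return []
    ts = pd.to_datetime(df[time_col], errors="coerce")
    glu = pd.to_numeric(df[glucose_col], errors="coerce")
    bad = ts.isna() | glu.isna() | (glu <= 0)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("%s: %d of %d rows malformed and skipped", path, n_bad, len(df))
        if n_bad / len(df) > max_bad_fraction:
            raise FormatError(f"{path}: {n_bad}/{len(df)} rows malformed "
                              f"(> {max_bad_fraction:.0%} allowed)")
    ok = df.loc[~bad, [id_col]].assign(_ts=ts[~bad], _glu=glu[~bad])
    traces = [
        CGMTrace.from_samples(str(pid), grp["_ts"], grp["_glu"], device=device)
        for pid, grp in ok.groupby(id_col, sort=True)
    ]
    return traces


# Column-name variants seen across LibreView export versions.
_LIBRE_TIME_COLS = ("Device Timestamp", "Time", "Meter Timestamp")
_LIBRE_HISTORIC_MGDL = ("Historic Glucose mg/dL", "Historic Glucose(mg/dL)")
_LIBRE_HISTORIC_MMOL = ("Historic Glucose mmol/L", "Historic Glucose(mmol/L)")
_LIBRE_RECORD_TYPE = "Record Type"
_LIBRE_HISTORIC_RECORD_TYPE = "0"


def read_libreview_csv(path, *, participant_id: str | None = None) -> CGMTrace:
    """Read a LibreView export CSV into a single CGM trace.

    The export starts with a free-form metadata preamble; the true header
    is located by searching for a known device-timestamp column name.
    Only *historic* glucose rows (record type 0) enter the trace; scan
    and note rows are dropped.  ``participant_id`` defaults to the file
    stem.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8-sig") as fh:
        lines = fh.readlines()
    header_row = None
    for i, line in enumerate(lines):
        if any(col in line for col in _LIBRE_TIME_COLS):
            header_row = i
            break
    if header_row is None:
        raise FormatError(f"{path}: no LibreView header row found "
                          f"(expected a column like 'Device Timestamp')")
    df = pd.read_csv(path, skiprows=header_row, dtype=str, encoding="utf-8-sig")
    time_col = next((c for c in _LIBRE_TIME_COLS if c in df.columns), None)
    if time_col is None:
        raise FormatError(f"{path}: no device-timestamp column in header")
    glucose_col = next((c for c in _LIBRE_HISTORIC_MGDL if c in df.columns), None)
    if glucose_col is None:
        if any(c in df.columns for c in _LIBRE_HISTORIC_MMOL):
            raise UnitError(f"{path}: historic glucose is in mmol/L; only mg/dL "
                            f"exports are supported (no unit conversion is performed)")
        raise FormatError(f"{path}: expected a historic-glucose column "
                          f"(one of {_LIBRE_HISTORIC_MGDL})")
    if _LIBRE_RECORD_TYPE in df.columns:
        df = df[df[_LIBRE_RECORD_TYPE].astype(str).str.strip() == _LIBRE_HISTORIC_RECORD_TYPE]
    ts = pd.to_datetime(df[time_col], errors="coerce")
    glu = pd.to_numeric(df[glucose_col], errors="coerce")
    keep = ~(ts.isna() | glu.isna())
    pid = participant_id if participant_id is not None else path.stem
    return CGMTrace.from_samples(pid, ts[keep], glu[keep], device="FreeStyle Libre Pro")


def write_long_csv(traces: Iterable[CGMTrace], path) -> None:
    """Write traces to the generic long CSV dialect (glucose to 1 dp)."""
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "participant_id": tr.participant_id,
            "timestamp": tr.samples.index.strftime("%Y-%m-%dT%H:%M"),
            "glucose_mgdl": np.round(tr.samples.to_numpy(), 1),
        }))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["participant_id", "timestamp", "glucose_mgdl"])
    out.to_csv(path, index=False)


def split_days(trace: CGMTrace) -> list[DayTrace]:
    """Partition a trace into calendar days, in chronological order.

    The union of the returned day samples is exactly the trace's samples;
    a boundary sample stamped 00:00 belongs to the new day.
    """
    if len(trace) == 0:
        return []
    return [DayTrace(day.date(), grp)
            for day, grp in trace.samples.groupby(trace.samples.index.normalize())]


def infer_sampling_interval_min(trace: CGMTrace) -> float:
    """Median inter-sample gap in minutes (the device's nominal cadence)."""
    if len(trace) < 2:
        raise ValueError("need at least two samples to infer a sampling interval")
    diffs = np.diff(trace.samples.index.asi8) / (60 * 1e9)
    return float(np.median(diffs))


@dataclass(frozen=True)
class WearCheck:
    """Outcome of the minimum-wear-time requirement."""

    passed: bool
    usable_days: int

    def __iter__(self):  # allow ``ok, n = passes_wear_requirement(...)``
        return iter((self.passed, self.usable_days))


def passes_wear_requirement(trace: CGMTrace, min_days: int = 10,
                            min_fraction: float = 0.7,
                            sampling_interval_min: float | None = None) -> WearCheck:
    """Check the consensus-style wear requirement for a trace.

    A day is *usable* when it holds at least ``min_fraction`` of the
    nominal samples per day at the device's sampling interval (inferred
    from the trace when not given).  The requirement passes when at least
    ``min_days`` usable days exist.
    """
    days = split_days(trace)
    if not days:
        return WearCheck(False, 0)
    if sampling_interval_min is None:
        sampling_interval_min = infer_sampling_interval_min(trace)
    nominal = 1440.0 / sampling_interval_min
    need = min_fraction * nominal - 1e-9
    usable = sum(1 for d in days if len(d) >= need)
    return WearCheck(usable >= min_days, usable)
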