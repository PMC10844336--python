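"""Rule-based detection of the start of breakfast on a CGM day.

Three rules define a breakfast: (i) the start lies between 05:00 and
11:00; (ii) the glucose rise from start to the post-start peak is at
least +40 mg/dL; (iii) when several segments qualify, the earliest one
is the breakfast.  Candidate segments are local-minimum-to-local-maximum
excursions of the raw sampled curve: each candidate starts at a local
minimum inside the window, and its peak is the highest sample within a
3-hour horizon after the start, truncated at the next local minimum.

Extrema are found on the raw samples without smoothing.  Plateaus are
collapsed: the earliest sample of a flat minimum (or maximum) is taken
as the extremum, which keeps detection deterministic on coarse 15-minute
data.  A day-boundary sample counts as a minimum when its single
neighbour is higher; an entirely flat day has no extrema and therefore
no candidates.

Manual annotations, when available, take precedence over automatic
detection: the segment is anchored at the sample nearest the annotated
start and rules (i)-(ii) are still applied as filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import time as Time, timedelta
from typing import Optional

import numpy as np
import pandas as pd

from .io import DayTrace

__all__ = [
    "BreakfastRules",
    "BreakfastSegment",
    "AnnotationError",
    "candidate_segments",
    "detect_breakfast",
    "apply_annotations",
    "breakfast_for_day",
]


class AnnotationError(ValueError):
    """A manual breakfast annotation cannot be matched to the trace."""


@dataclass(frozen=True)
class BreakfastRules:
    """Parameters of the three breakfast rules (defaults as primary analysis)."""

    window_start: Time = Time(5, 0)
    window_end: Time = Time(11, 0)
    min_rise: float = 40.0           # mg/dL, rule (ii)
    peak_search_horizon: timedelta = timedelta(hours=3)

    def __post_init__(self) -> None:
        if self.window_start >= self.window_end:
            raise ValueError("window_start must precede window_end")
        if self.min_rise <= 0:
            raise ValueError("min_rise must be positive")


@dataclass(frozen=True)
class BreakfastSegment:
    """A detected breakfast excursion (times are full timestamps)."""

    start_time: pd.Timestamp
    start_glucose: float
    peak_time: pd.Timestamp
    peak_glucose: float

    @property
    def rise(self) -> float:
        return self.peak_glucose - self.start_glucose


def _plateau_runs(values: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal runs of equal consecutive values as (start, end_exclusive, value)."""
    runs = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            runs.append((start, i, float(values[start])))
            start = i
    return runs


def local_min_positions(values: np.ndarray) -> list[int]:
    """Indices of local minima (earliest sample of each flat minimum).

    Interior minima are strict against both neighbouring runs; a boundary
    run qualifies when its single neighbour is higher.  A constant series
    has no minima.
    """
    if len(values) == 0:
        return []
    runs = _plateau_runs(np.asarray(values, dtype=float))
    if len(runs) == 1:
        return []
    mins = []
    for k, (s, _e, v) in enumerate(runs):
        left_ok = k == 0 or runs[k - 1][2] > v
        right_ok = k == len(runs) - 1 or runs[k + 1][2] > v
        if left_ok and right_ok:
            mins.append(s)
    return mins


def candidate_segments(day: DayTrace, rules: BreakfastRules) -> list[BreakfastSegment]:
    """Breakfast candidates on a day, ordered by start time.

    Each candidate starts at a local minimum whose clock time falls in
    [window_start, window_end]; its peak is the maximum sample after the
    start, within the peak-search horizon and before the next local
    minimum (earliest sample wins a tied maximum).  Days with fewer than
    two samples in the window yield no candidates.
    """
    idx = day.samples.index
    vals = day.samples.to_numpy(dtype=float)
    times = [t.time() for t in idx]
    in_window = [rules.window_start <= t <= rules.window_end for t in times]
    if sum(in_window) < 2:
        return []
    mins = local_min_positions(vals)
    out: list[BreakfastSegment] = []
    for pos, m in enumerate(mins):
        if not in_window[m]:
            continue
        next_min = mins[pos + 1] if pos + 1 < len(mins) else len(vals)
        horizon_end = idx[m] + rules.peak_search_horizon
        stop = m + 1
        while stop < next_min and idx[stop] <= horizon_end:
            stop += 1
        if stop == m + 1:
            continue  # no sample to form a peak
        seg_vals = vals[m + 1:stop]
        j = m + 1 + int(np.argmax(seg_vals))  # argmax keeps the earliest tie
        if vals[j] < vals[m]:
            continue
        out.append(BreakfastSegment(idx[m], float(vals[m]), idx[j], float(vals[j])))
    return out


def detect_breakfast(day: DayTrace, rules: BreakfastRules) -> Optional[BreakfastSegment]:
    """Earliest candidate satisfying rules (i)-(ii), or ``None``.

    Absence is a value: a day without a qualifying segment simply has no
    valid breakfast peak and is excluded from downstream DP analysis.
    """
    for seg in candidate_segments(day, rules):
        if seg.rise >= rules.min_rise:
            return seg
    return None


def apply_annotations(day: DayTrace, annotated_start: Time,
                      rules: BreakfastRules) -> Optional[BreakfastSegment]:
    """Build a breakfast segment anchored at a manual annotation.

    The segment starts at the sample nearest the annotated clock time
    (which must lie within one sampling interval); its peak is the
    maximum sample within the peak-search horizon after the start.
    Rules (i) and (ii) are then applied as filters; a failing annotated
    segment yields ``None`` (the day has no valid breakfast).
    """
    idx = day.samples.index
    if len(idx) < 2:
        raise AnnotationError(f"{day.date}: too few samples to anchor an annotation")
    target = pd.Timestamp.combine(pd.Timestamp(day.date), annotated_start)
    gaps = np.abs((idx - target).asi8)
    p = int(np.argmin(gaps))
    interval_ns = np.median(np.diff(idx.asi8))
    if gaps[p] > interval_ns:
        raise AnnotationError(
            f"{day.date}: no sample within one sampling interval of "
            f"annotated breakfast start {annotated_start}")
    start_t = idx[p]
    if not (rules.window_start <= start_t.time() <= rules.window_end):
        return None
    horizon_end = start_t + rules.peak_search_horizon
    after = day.samples.iloc[p + 1:]
    after = after[after.index <= horizon_end]
    if after.empty:
        return None
    j = int(np.argmax(after.to_numpy()))
    seg = BreakfastSegment(start_t, float(day.samples.iloc[p]),
                           after.index[j], float(after.iloc[j]))
    return seg if seg.rise >= rules.min_rise else None


def breakfast_for_day(day: DayTrace, rules: BreakfastRules,
                      annotated_start: Time | None = None) -> Optional[BreakfastSegment]:
    """Annotation-first breakfast resolution for one day."""
    if annotated_start is not None:
        return apply_annotations(day, annotated_start, rules)
    return detect_breakfast(day, rules)
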