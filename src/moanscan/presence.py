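"""Daily/monthly acoustic presence, bouts, and recording-effort accounting.

Verified detections are binned by UTC calendar day against a log of when the
observatory actually recorded.  Days without effort cannot produce
detections; they are flagged so that absence of calls is never confused with
absence of recording.  A bout is a maximal run of consecutive days each with
at least one verified detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd

__all__ = [
    "EffortLog",
    "Bout",
    "BoutResult",
    "daily_presence",
    "monthly_counts",
    "find_bouts",
]


@dataclass
class EffortLog:
    """Non-overlapping, sorted UTC intervals during which recording ran."""

    intervals: list[tuple[datetime, datetime]]

    def __post_init__(self) -> None:
        ivs = sorted(
            ((_utc(a), _utc(b)) for a, b in self.intervals), key=lambda p: p[0]
        )
        for a, b in ivs:
            if b <= a:
                raise ValueError(f"empty or reversed effort interval {a} .. {b}")
        for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ValueError("effort intervals overlap")
        self.intervals = ivs

    @classmethod
    def from_segments(cls, segments) -> "EffortLog":
        """Build from calibrated audio segments (one interval each)."""
        return cls([(s.start_time, s.end_time) for s in segments])

    def total_seconds(self) -> float:
        return sum((b - a).total_seconds() for a, b in self.intervals)

    def recorded_seconds_by_day(self) -> pd.Series:
        """Seconds of recording per UTC calendar day over the effort span."""
        if not self.intervals:
            return pd.Series(dtype=float)
        start = self.intervals[0][0].date()
        end = (self.intervals[-1][1] - timedelta(microseconds=1)).date()
        days = pd.date_range(start, end, freq="D").date
        out = pd.Series(0.0, index=pd.Index(days, name="date"))
        for a, b in self.intervals:
            d = a.date()
            while d <= (b - timedelta(microseconds=1)).date():
                day_start = datetime.combine(d, datetime.min.time(), tzinfo=timezone.utc)
                day_end = day_start + timedelta(days=1)
                out[d] += (min(b, day_end) - max(a, day_start)).total_seconds()
                d += timedelta(days=1)
        return out


@dataclass(frozen=True)
class Bout:
    """A run of consecutive calendar days each holding >=1 verified call."""

    start: date
    end: date
    length: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("bout end precedes start")


@dataclass(frozen=True)
class BoutResult:
    bouts: list[Bout]
    singleton_days: list[date]


def _utc(t: datetime) -> datetime:
    return t.replace(tzinfo=timezone.utc) if t.tzinfo is None else t


def daily_presence(events, effort: EffortLog) -> pd.DataFrame:
    """Bin verified detections into a per-day presence table.

    Returns a DataFrame indexed by UTC date with columns
    ``detection_count`` and ``recorded_seconds``, one row for every calendar
    day in the effort span (extended to cover any stray events).  Events
    falling outside all effort intervals are kept — small clock skew between
    the detector and the effort log is tolerated — but trigger a warning.
    """
    for ev in events:
        if ev.verified != "true":
            raise ValueError("daily_presence expects verified events only; "
                             "filter with detector.filter_verified first")
    recorded = effort.recorded_seconds_by_day()
    ev_dates = [_utc(ev.time).date() for ev in events]
    for ev, d in zip(events, ev_dates):
        t = _utc(ev.time)
        if not any(a <= t < b for a, b in effort.intervals):
            warnings.warn(f"event at {t.isoformat()} lies outside logged effort; "
                          "included anyway", stacklevel=2)
    all_dates = list(recorded.index)
    span = sorted(set(all_dates) | set(ev_dates))
    if span:
        days = pd.date_range(span[0], span[-1], freq="D").date
    else:
        days = []
    idx = pd.Index(days, name="date")
    counts = pd.Series(0, index=idx, dtype=int)
    for d in ev_dates:
        counts[d] += 1
    rec = recorded.reindex(idx, fill_value=0.0)
    return pd.DataFrame({"detection_count": counts, "recorded_seconds": rec})


def monthly_counts(series: pd.DataFrame) -> pd.DataFrame:
    """Calendar-month totals with effort fractions.

    Columns: ``detection_count`` (raw sum — the headline number),
    ``recorded_seconds``, ``effort_fraction`` of the full month,
    ``low_effort`` flag (effort < 50%), and ``detections_per_recorded_hour``
    for effort-aware comparison across months.
    """
    if series.empty:
        return pd.DataFrame(columns=["detection_count", "recorded_seconds",
                                     "effort_fraction", "low_effort",
                                     "detections_per_recorded_hour"])
    df = series.copy()
    df["month"] = pd.PeriodIndex([pd.Period(d, freq="M") for d in df.index], freq="M")
    g = df.groupby("month")[["detection_count", "recorded_seconds"]].sum()
    month_seconds = np.array([p.days_in_month * 86400.0 for p in g.index])
    g["effort_fraction"] = g["recorded_seconds"] / month_seconds
    g["low_effort"] = g["effort_fraction"] < 0.5
    hours = g["recorded_seconds"] / 3600.0
    g["detections_per_recorded_hour"] = np.where(
        hours > 0, g["detection_count"] / hours.replace(0, np.nan), np.nan)
    return g


def find_bouts(series: pd.DataFrame, min_length: int = 2,
               bridge_no_effort: bool = False) -> BoutResult:
    """Find maximal runs of consecutive detection-days.

    A day with effort but no detections always ends a run.  A day with zero
    recorded effort also ends a run by default (conservative: we cannot know
    whether calling continued); with ``bridge_no_effort`` runs continue
    across recording outages, in which case a bout's ``length`` counts its
    detection days only and may be smaller than its calendar span.

    Runs shorter than ``min_length`` days are reported separately as
    singleton days rather than bouts.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    bouts: list[Bout] = []
    singles: list[date] = []
    run: list[date] = []

    def close() -> None:
        nonlocal run
        if not run:
            return
        if len(run) >= min_length:
            length = len(run) if bridge_no_effort else (run[-1] - run[0]).days + 1
            bouts.append(Bout(run[0], run[-1], length))
        else:
            singles.extend(run)
        run = []

    for d, row in series.iterrows():
        has_det = row["detection_count"] > 0
        has_eff = row["recorded_seconds"] > 0
        if has_det:
            run.append(d)
        elif has_eff:
            close()
        elif not bridge_no_effort:
            close()
        # else: no-effort day inside a bridged run — neither breaks nor extends
    close()
    return BoutResult(bouts, singles)
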