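"""Turn electronic adherence monitor (EAM/MEMS) dose-event logs into the
per-participant quantities the run model consumes.

An EAM is a pill-bottle cap that timestamps every opening.  From a
participant's opening log over an n-day observation window we derive:

* a daily binary series (a day counts as "taken" if >= 1 opening falls in it),
* average adherence = openings / prescribed doses, capped at 1,
* an interruption flag under either of two rules: a run of >= r fully
  missed days (day-run rule, matching the model's discretisation) or any
  gap > 72 h between consecutive openings (timestamp rule — the literal
  reading of "zero adherence for more than 72 hours"),
* exclusion bands (adherence so low a run is combinatorially forced, or so
  high one is impossible — see :func:`tirisk.exact_oracle.guaranteed_bounds`),
* binned interval counts for goodness-of-fit testing.

Day boundaries are anchored at the therapy-start clock time with half-open
[start + i*24h, start + (i+1)*24h) spans; timestamps are naive (no time-zone
arithmetic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model_core import DEFAULT_INTERVALS, AdherenceInterval

__all__ = [
    "EventLog",
    "DailyAdherenceSeries",
    "ParticipantSummary",
    "BinnedCohort",
    "daily_series_from_events",
    "average_adherence",
    "max_zero_run",
    "detect_interruption",
    "summarize_log",
    "summarize_series",
    "apply_exclusions",
    "bin_cohort",
    "read_events_csv",
    "read_daily_csv",
    "write_daily_csv",
    "summaries_to_frame",
    "write_summary_csv",
    "read_summary_csv",
]

logger = logging.getLogger(__name__)

HOURS_PER_DAY = 24.0


@dataclass
class EventLog:
    """One participant's bottle-opening timestamps over an observation window."""

    participant_id: str
    openings: list[datetime]
    therapy_start: datetime
    doses_per_day: int = 2
    window_days: int = 90

    def __post_init__(self) -> None:
        if self.doses_per_day < 1:
            raise ValueError("doses_per_day must be >= 1")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        self.openings = sorted(self.openings)

    @property
    def window_end(self) -> datetime:
        return self.therapy_start + timedelta(days=self.window_days)

    def openings_in_window(self) -> tuple[list[datetime], int]:
        """(openings inside [start, end), count of out-of-window records)."""
        inside = [t for t in self.openings if self.therapy_start <= t < self.window_end]
        return inside, len(self.openings) - len(inside)


@dataclass
class DailyAdherenceSeries:
    """Binary taken/missed vector, one entry per observation day."""

    participant_id: str
    taken: np.ndarray

    def __post_init__(self) -> None:
        self.taken = np.asarray(self.taken, dtype=np.int8)
        if not np.isin(self.taken, (0, 1)).all():
            raise ValueError("taken entries must be 0 or 1")

    @property
    def n_days(self) -> int:
        return int(self.taken.size)


@dataclass
class ParticipantSummary:
    participant_id: str
    average_adherence: float
    interrupted: bool
    max_miss_run: int
    max_gap_hours: float | None = None
    adherence_capped: bool = False


@dataclass
class BinnedCohort:
    """Participants grouped into adherence intervals with interruption counts."""

    intervals: Sequence[AdherenceInterval]
    n_i: list[int]
    k_i: list[int]
    outside: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.intervals) == len(self.n_i) == len(self.k_i)):
            raise ValueError("intervals, n_i and k_i must have equal length")
        if any(k > n for n, k in zip(self.n_i, self.k_i)):
            raise ValueError("interrupted count exceeds interval headcount")

    @property
    def total(self) -> int:
        return sum(self.n_i)


def daily_series_from_events(log: EventLog) -> DailyAdherenceSeries:
    """Collapse opening timestamps to a daily binary series.

    Day i spans [start + i*24h, start + (i+1)*24h); an opening exactly on a
    boundary belongs to the later day.  Openings outside the window are
    dropped with a logged warning.
    """
    inside, n_outside = log.openings_in_window()
    if n_outside:
        logger.warning(
            "participant %s: %d opening(s) outside the %d-day window dropped",
            log.participant_id,
            n_outside,
            log.window_days,
        )
    taken = np.zeros(log.window_days, dtype=np.int8)
    for t in inside:
        day = int((t - log.therapy_start) / timedelta(days=1))
        taken[day] = 1
    return DailyAdherenceSeries(participant_id=log.participant_id, taken=taken)


def average_adherence(log: EventLog) -> tuple[float, bool]:
    """Openings divided by prescribed doses, capped at 1.

    Returns (adherence, capped).  Opening counts can exceed the prescription
    (pocket dosing, curiosity openings), so values above 1 are capped and
    the cap flagged.
    """
    inside, _ = log.openings_in_window()
    prescribed = log.doses_per_day * log.window_days
    raw = len(inside) / prescribed
    return min(raw, 1.0), raw > 1.0


def max_zero_run(taken: np.ndarray) -> int:
    """Length of the longest run of zeros in a binary vector."""
    longest = current = 0
    for v in np.asarray(taken).ravel():
        current = current + 1 if v == 0 else 0
        longest = max(longest, current)
    return longest


def _max_gap_hours(log: EventLog) -> float:
    """Largest gap (hours) between consecutive openings, including the edges
    therapy_start -> first opening and last opening -> window end."""
    inside, _ = log.openings_in_window()
    anchors = [log.therapy_start, *inside, log.window_end]
    gaps = [
        (b - a) / timedelta(hours=1) for a, b in zip(anchors, anchors[1:])
    ]
    return max(gaps)


def detect_interruption(
    obj: DailyAdherenceSeries | EventLog,
    rule: str = "day-run",
    r: int = 3,
    threshold_hours: float = 72.0,
) -> tuple[bool, int | None, float | None]:
    """Flag a treatment interruption under the chosen rule.

    day-run rule (requires a daily series or a log to collapse): interrupted
    iff the longest run of fully missed days is >= r.  timestamp rule
    (requires an :class:`EventLog`): interrupted iff any inter-opening gap —
    edges included — exceeds ``threshold_hours``.

    Returns (interrupted, max_miss_run, max_gap_hours); the entry not
    relevant to the chosen rule is None unless computable for free.
    """
    if rule == "day-run":
        series = obj if isinstance(obj, DailyAdherenceSeries) else daily_series_from_events(obj)
        run = max_zero_run(series.taken)
        return run >= r, run, None
    if rule == "timestamp-gap":
        if not isinstance(obj, EventLog):
            raise TypeError("timestamp-gap rule requires an EventLog")
        gap = _max_gap_hours(obj)
        return gap > threshold_hours, None, gap
    raise ValueError(f"unknown rule {rule!r}")


def summarize_log(
    log: EventLog, rule: str = "day-run", r: int = 3, threshold_hours: float = 72.0
) -> ParticipantSummary:
    """Full per-participant summary from an event log."""
    adherence, capped = average_adherence(log)
    series = daily_series_from_events(log)
    run = max_zero_run(series.taken)
    gap = _max_gap_hours(log) if log.openings else float(log.window_days * 24)
    if rule == "day-run":
        interrupted = run >= r
    elif rule == "timestamp-gap":
        interrupted = gap > threshold_hours
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return ParticipantSummary(
        participant_id=log.participant_id,
        average_adherence=adherence,
        interrupted=interrupted,
        max_miss_run=run,
        max_gap_hours=gap,
        adherence_capped=capped,
    )


def summarize_series(
    series: DailyAdherenceSeries, doses_per_day: int = 2, r: int = 3
) -> ParticipantSummary:
    """Per-participant summary from a daily series alone (day-run rule).

    Average adherence from a binary series is taken-days / window-days: a
    day either contributes all its prescribed doses or none, so the dose
    multiplier cancels.
    """
    run = max_zero_run(series.taken)
    return ParticipantSummary(
        participant_id=series.participant_id,
        average_adherence=float(series.taken.mean()),
        interrupted=run >= r,
        max_miss_run=run,
    )


def apply_exclusions(
    summaries: Iterable[ParticipantSummary],
    lower: float = 0.40,
    sparse_band: tuple[float, float] = (0.333, 0.40),
    never_band: float = 0.967,
) -> tuple[list[ParticipantSummary], list[tuple[ParticipantSummary, str]]]:
    """Partition participants into kept [lower, never_band) and excluded bands.

    Below the sparse band a 3-day run is combinatorially forced (the
    always-interrupt band); at or above ``never_band`` one is impossible;
    the sparse band is dropped for insufficient data.  Exclusion reasons are
    recorded per participant.
    """
    kept: list[ParticipantSummary] = []
    excluded: list[tuple[ParticipantSummary, str]] = []
    for s in summaries:
        a = s.average_adherence
        if a >= never_band:
            excluded.append((s, "never-interrupt band"))
        elif a < sparse_band[0]:
            excluded.append((s, "always-interrupt band"))
        elif a < lower:
            excluded.append((s, "sparse band"))
        else:
            kept.append(s)
    return kept, excluded


def bin_cohort(
    summaries: Iterable[ParticipantSummary],
    intervals: Sequence[AdherenceInterval] = DEFAULT_INTERVALS,
) -> BinnedCohort:
    """Count participants and interruptions per half-open adherence interval.

    Participants falling outside every interval are reported on the result,
    never silently dropped.
    """
    n_i = [0] * len(intervals)
    k_i = [0] * len(intervals)
    outside: list[str] = []
    for s in summaries:
        for j, interval in enumerate(intervals):
            if interval.contains(s.average_adherence):
                n_i[j] += 1
                k_i[j] += int(s.interrupted)
                break
        else:
            outside.append(s.participant_id)
    return BinnedCohort(intervals=intervals, n_i=n_i, k_i=k_i, outside=outside)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_events_csv(
    path: str | Path,
    doses_per_day: int = 2,
    window_days: int = 90,
    therapy_start: datetime | str | None = None,
) -> list[EventLog]:
    """Read an events CSV (columns: participant_id, opened_at ISO-8601).

    ``therapy_start`` applies to every participant; if omitted, each
    participant's window is anchored at midnight of their first opening day.
    """
    df = pd.read_csv(path)
    required = {"participant_id", "opened_at"}
    if not required.issubset(df.columns):
        raise ValueError(f"events CSV must have columns {sorted(required)}")
    df["opened_at"] = pd.to_datetime(df["opened_at"])
    if therapy_start is not None:
        therapy_start = pd.Timestamp(therapy_start).to_pydatetime()
    logs = []
    for pid, group in df.groupby("participant_id", sort=True):
        openings = [t.to_pydatetime() for t in group["opened_at"].sort_values()]
        start = therapy_start or openings[0].replace(
            hour=0, minute=0, second=0, microsecond=0
        )
        logs.append(
            EventLog(
                participant_id=str(pid),
                openings=openings,
                therapy_start=start,
                doses_per_day=doses_per_day,
                window_days=window_days,
            )
        )
    return logs


def read_daily_csv(path: str | Path) -> list[DailyAdherenceSeries]:
    """Read a daily CSV (columns: participant_id, day_index, dose_taken)."""
    df = pd.read_csv(path)
    required = {"participant_id", "day_index", "dose_taken"}
    if not required.issubset(df.columns):
        raise ValueError(f"daily CSV must have columns {sorted(required)}")
    out = []
    for pid, group in df.groupby("participant_id", sort=True):
        group = group.sort_values("day_index")
        expected = np.arange(len(group))
        if not (group["day_index"].to_numpy() == expected).all():
            raise ValueError(f"participant {pid}: day_index must be 0..n-1 contiguous")
        out.append(
            DailyAdherenceSeries(
                participant_id=str(pid), taken=group["dose_taken"].to_numpy()
            )
        )
    return out


def write_daily_csv(series: Iterable[DailyAdherenceSeries], path: str | Path) -> None:
    rows = [
        {"participant_id": s.participant_id, "day_index": i, "dose_taken": int(v)}
        for s in series
        for i, v in enumerate(s.taken)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def summaries_to_frame(summaries: Iterable[ParticipantSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": s.participant_id,
            "average_adherence": s.average_adherence,
            "interrupted": int(s.interrupted),
            "max_miss_run": s.max_miss_run,
        }
        for s in summaries
    )


def write_summary_csv(summaries: Iterable[ParticipantSummary], path: str | Path) -> None:
    summaries_to_frame(summaries).to_csv(path, index=False)


def read_summary_csv(path: str | Path) -> list[ParticipantSummary]:
    df = pd.read_csv(path)
    required = {"participant_id", "average_adherence", "interrupted"}
    if not required.issubset(df.columns):
        raise ValueError(f"summary CSV must have columns {sorted(required)}")
    return [
        ParticipantSummary(
            participant_id=str(row.participant_id),
            average_adherence=float(row.average_adherence),
            interrupted=bool(row.interrupted),
            max_miss_run=int(getattr(row, "max_miss_run", -1)),
        )
        for row in df.itertuples()
    ]
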