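"""Reading, validation, deduplication and light-phase slicing of RFID event logs.

An event log is the raw observational unit of home-cage monitoring: every time
a transponder-tagged animal passes a ring antenna, the system records
``(timestamp, antenna_id, animal_id)``.  This module turns delimited text into
a validated, time-sorted :class:`EventLog`, optionally collapses hardware
re-reads of a stationary animal (:func:`deduplicate`), and slices out the
nightly dark phase over which roaming entropy is computed
(:func:`extract_dark_phase`).

Timestamps are naive local clock times throughout; the study site runs a
single clock and seasonal schedule changes are expressed in the light-schedule
table, not via timezone arithmetic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventLogError",
    "EventLog",
    "LightRegime",
    "LightSchedule",
    "parse_event_log",
    "write_event_log",
    "deduplicate",
    "extract_dark_phase",
    "iter_nights",
]

COLUMNS = ["timestamp", "antenna_id", "animal_id"]


class EventLogError(ValueError):
    """Raised for malformed or out-of-layout event records.

    Carries a per-line error report in :attr:`report` so that no bad line is
    silently dropped: each entry is ``(line_number, reason)`` with 1-based
    line numbers counting the header.
    """

    def __init__(self, report: list[tuple[int, str]]):
        self.report = report
        head = "; ".join(f"line {ln}: {msg}" for ln, msg in report[:5])
        more = f" (+{len(report) - 5} more)" if len(report) > 5 else ""
        super().__init__(f"{len(report)} invalid event record(s): {head}{more}")


@dataclass
class EventLog:
    """Time-sorted antenna detections plus the installed-antenna count ``layout_k``."""

    events: pd.DataFrame
    layout_k: int

    def __post_init__(self) -> None:
        if self.layout_k < 1:
            raise ValueError("layout_k must be >= 1")
        missing = [c for c in COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"event frame missing columns {missing}")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def animals(self) -> list[str]:
        return sorted(self.events["animal_id"].unique())

    def for_animal(self, animal_id: str) -> pd.DataFrame:
        return self.events[self.events["animal_id"] == animal_id]

    def between(self, start: datetime, end: datetime) -> "EventLog":
        """Events in the half-open interval ``[start, end)``."""
        ts = self.events["timestamp"]
        sel = self.events[(ts >= start) & (ts < end)]
        return EventLog(sel.reset_index(drop=True), self.layout_k)


def parse_event_log(source: str | Path | io.TextIOBase, layout_k: int) -> EventLog:
    """Parse a ``timestamp,antenna_id,animal_id`` CSV into an :class:`EventLog`.

    Parameters
    ----------
    source:
        Path to a CSV file, a file-like object, or the CSV text itself
        (detected by an embedded newline / header).
    layout_k:
        Number of installed antennas; antenna ids must lie in ``1..layout_k``.

    The result is stably sorted by timestamp.  All malformed lines are
    collected and raised together as :class:`EventLogError`; an empty input
    (header only, or nothing) yields an empty log.
    """
    if isinstance(source, (io.TextIOBase, io.StringIO)):
        text = source.read()
    elif isinstance(source, Path):
        text = source.read_text()
    else:
        s = str(source)
        # A string is a path only if it names an existing file; otherwise it
        # is taken as CSV text (possibly a single record or empty).
        if "\n" not in s and s and Path(s).is_file():
            text = Path(s).read_text()
        else:
            text = s

    lines = [ln for ln in text.splitlines()]
    # Optional header line.
    start_idx = 0
    if lines and lines[0].replace(" ", "").lower().startswith("timestamp,"):
        start_idx = 1

    stamps: list[datetime] = []
    antennas: list[int] = []
    animals: list[str] = []
    report: list[tuple[int, str]] = []
    for offset, raw in enumerate(lines[start_idx:]):
        lineno = start_idx + offset + 1
        if not raw.strip():
            continue
        parts = [p.strip() for p in raw.split(",")]
        if len(parts) != 3:
            report.append((lineno, f"expected 3 fields, got {len(parts)}"))
            continue
        ts_s, ant_s, animal = parts
        try:
            ts = datetime.fromisoformat(ts_s)
        except ValueError:
            report.append((lineno, f"unparseable timestamp {ts_s!r}"))
            continue
        if ts.tzinfo is not None:
            report.append((lineno, "timestamps must be timezone-free local times"))
            continue
        try:
            ant = int(ant_s)
        except ValueError:
            report.append((lineno, f"non-integer antenna id {ant_s!r}"))
            continue
        if not 1 <= ant <= layout_k:
            report.append((lineno, f"antenna {ant} outside layout 1..{layout_k}"))
            continue
        if not animal:
            report.append((lineno, "empty animal id"))
            continue
        stamps.append(ts)
        antennas.append(ant)
        animals.append(animal)

    if report:
        raise EventLogError(report)

    df = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(stamps),
            "antenna_id": np.asarray(antennas, dtype=np.int64),
            "animal_id": animals,
        }
    )
    df = df.sort_values("timestamp", kind="stable").reset_index(drop=True)
    return EventLog(df, layout_k)


def write_event_log(log: EventLog, path: str | Path | None = None) -> str:
    """Serialize to the canonical CSV dialect; returns the text, optionally writing it."""
    out = io.StringIO()
    out.write("timestamp,antenna_id,animal_id\n")
    for ts, ant, animal in log.events.itertuples(index=False):
        out.write(f"{pd.Timestamp(ts).isoformat()},{ant},{animal}\n")
    text = out.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def deduplicate(log: EventLog, refractory_s: float = 1.0) -> EventLog:
    """Collapse antenna re-reads of a stationary animal.

    Within each ``(animal, antenna)`` stream an event is kept only if it is at
    least ``refractory_s`` seconds after the previously *kept* event of that
    stream; events at different antennas are never merged.  ``refractory_s=0``
    is the raw-count mode and returns the log unchanged.  The chain rule makes
    the operation idempotent.
    """
    if refractory_s < 0:
        raise ValueError("refractory_s must be >= 0")
    if refractory_s == 0 or len(log) == 0:
        return EventLog(log.events.copy().reset_index(drop=True), log.layout_k)

    df = log.events
    keep = np.zeros(len(df), dtype=bool)
    t = df["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64)
    refractory_ns = int(round(refractory_s * 1e9))
    for _, idx in df.groupby(["animal_id", "antenna_id"], sort=False).indices.items():
        idx = np.sort(np.asarray(idx))
        last_kept = None
        for i in idx:
            if last_kept is None or t[i] - last_kept >= refractory_ns:
                keep[i] = True
                last_kept = t[i]
    out = df[keep].reset_index(drop=True)
    return EventLog(out, log.layout_k)


@dataclass(frozen=True)
class LightRegime:
    """One seasonal lighting regime: applies to nights with lights-off date in
    ``[start_date, end_date]`` (inclusive calendar dates)."""

    start_date: date
    end_date: date
    lights_on: time
    lights_off: time

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError("regime end_date before start_date")
        on = datetime.combine(date(2000, 1, 1), self.lights_on)
        off = datetime.combine(date(2000, 1, 1), self.lights_off)
        light_h = ((off - on).total_seconds() / 3600.0) % 24.0
        if abs(light_h - 12.0) > 1e-9:
            raise ValueError(
                f"regime must define a 12 h light / 12 h dark cycle, got {light_h} h light"
            )


@dataclass
class LightSchedule:
    """Non-overlapping seasonal lighting regimes covering the study span."""

    regimes: Sequence[LightRegime]

    def __post_init__(self) -> None:
        regs = sorted(self.regimes, key=lambda r: r.start_date)
        for a, b in zip(regs, regs[1:]):
            if b.start_date <= a.end_date:
                raise ValueError("light regimes overlap")
        self.regimes = list(regs)

    def regime_for(self, night_date: date) -> LightRegime:
        for r in self.regimes:
            if r.start_date <= night_date <= r.end_date:
                return r
        raise KeyError(f"date {night_date} not covered by the light schedule")

    def dark_interval(self, night_date: date) -> tuple[datetime, datetime]:
        """Half-open ``[lights_off on night_date, lights_on on night_date+1)``.

        A night is labelled by its lights-off calendar date; the next
        morning's lights-on time is taken from whichever regime covers the
        next date (falling back to the night's regime at the schedule edge).
        """
        r = self.regime_for(night_date)
        start = datetime.combine(night_date, r.lights_off)
        next_day = night_date + timedelta(days=1)
        try:
            r_next = self.regime_for(next_day)
        except KeyError:
            r_next = r
        end = datetime.combine(next_day, r_next.lights_on)
        return start, end

    @classmethod
    def from_csv(cls, source: str | Path) -> "LightSchedule":
        """Read regimes from ``start_date,end_date,lights_on,lights_off`` lines."""
        s = str(source)
        if isinstance(source, Path) or ("\n" not in s and Path(s).is_file()):
            text = Path(s).read_text()
        else:
            text = s
        regimes = []
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("start_date") or line.startswith("#"):
                continue
            d0, d1, on, off = [p.strip() for p in line.split(",")]
            regimes.append(
                LightRegime(
                    date.fromisoformat(d0),
                    date.fromisoformat(d1),
                    time.fromisoformat(on),
                    time.fromisoformat(off),
                )
            )
        if not regimes:
            raise ValueError("empty light schedule")
        return cls(regimes)

    def to_csv(self) -> str:
        lines = ["start_date,end_date,lights_on,lights_off"]
        for r in self.regimes:
            lines.append(
                f"{r.start_date},{r.end_date},"
                f"{r.lights_on.isoformat('minutes')},{r.lights_off.isoformat('minutes')}"
            )
        return "\n".join(lines) + "\n"


def extract_dark_phase(log: EventLog, sched: LightSchedule, night_date: date) -> EventLog:
    """Events of the 12 h dark phase labelled by lights-off date ``night_date``."""
    start, end = sched.dark_interval(night_date)
    return log.between(start, end)


def iter_nights(
    log: EventLog, sched: LightSchedule, night_dates: Sequence[date]
) -> Iterator[tuple[date, EventLog]]:
    """Yield ``(night_date, dark-phase EventLog)`` for each requested night."""
    for d in night_dates:
        yield d, extract_dark_phase(log, sched, d)
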