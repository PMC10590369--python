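"""Reading trace logs and the two preprocessing filters.

A trace log has one row per event: an opaque actor id, a calendar date, and
a target-action token such as ``course_module>updated``.  Two filters are
applied before any modeling:

1. *General-use removal*: tokens that reflect generic platform use rather
   than a specific work task (logins, notifications, plain views) are
   dropped entirely.
2. *Low-activity-week removal*: an actor-week with fewer than 25 surviving
   events is dropped as a whole, since so few events do not form a
   meaningful weekly activity profile.

The threshold is applied after general-use removal: the removed tokens
correspond to general use of the system instead of a specific task, and the
threshold is meant to gate meaningful task activity.
"""

from __future__ import annotations

import csv
import datetime as _dt
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from traceclust.errors import FormatError

#: Target-action pairs that reflect general platform use, removed before
#: any analysis.
DEFAULT_REMOVAL_LIST: frozenset[str] = frozenset(
    {
        "user>loggedin",
        "user>loggedout",
        "notification>sent",
        "notification>viewed",
        "course>viewed",
        "course_module>viewed",
    }
)

#: Minimum number of (surviving) events an actor-week must have to be kept.
DEFAULT_MIN_WEEKLY_EVENTS: int = 25

EXPECTED_COLUMNS = ("actor_id", "date", "target_action")

_WS = re.compile(r"\s+")


@dataclass(frozen=True, slots=True)
class TraceEvent:
    """One timestamped actor/target/action record, the atomic log unit."""

    actor_id: str
    date: _dt.date
    target_action: str


@dataclass(frozen=True, slots=True)
class WeekedEvent:
    """A trace event with its date collapsed to an ISO (year, week) pair."""

    actor_id: str
    year: int
    week: int
    target_action: str


@dataclass
class ReadReport:
    """What happened while reading a log file."""

    n_rows: int = 0
    n_events: int = 0
    n_malformed: int = 0
    errors: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_events": self.n_events,
            "n_malformed": self.n_malformed,
            "errors": self.errors[:50],
        }


def normalize_token(raw: str) -> str:
    """Canonicalize a target-action token to ``target>action``.

    Whitespace around the separator is tolerated (logs are often printed as
    ``course_module > viewed``).  Raises :class:`FormatError` unless the
    token contains exactly one ``>`` separator.
    """
    token = _WS.sub("", raw.strip())
    if token.count(">") != 1:
        raise FormatError(
            f"target_action token {raw!r} must contain exactly one '>' separator"
        )
    target, action = token.split(">")
    if not target or not action:
        raise FormatError(f"target_action token {raw!r} has an empty side")
    return token


def parse_date(raw: str, dialect: str = "dayfirst") -> _dt.date:
    """Parse a calendar date.

    ``dialect='dayfirst'`` accepts ``17.6.2019`` (the form typical of
    European platform exports) and falls back to ISO ``2019-06-17``;
    ``dialect='iso'`` accepts ISO only.
    """
    raw = raw.strip()
    if dialect not in ("dayfirst", "iso"):
        raise ValueError(f"unknown date dialect {dialect!r}")
    if dialect == "dayfirst" and "." in raw:
        parts = raw.split(".")
        if len(parts) != 3:
            raise ValueError(f"cannot parse day-first date {raw!r}")
        day, month, year = (int(p) for p in parts)
        return _dt.date(year, month, day)
    return _dt.date.fromisoformat(raw)


def read_trace_log(
    path: str | Path,
    dialect: str = "dayfirst",
    delimiter: str = ",",
    max_error_fraction: float = 0.05,
) -> tuple[list[TraceEvent], ReadReport]:
    """Read a CSV trace log with header ``actor_id,date,target_action``.

    Malformed rows (bad date, bad token) are collected in the report rather
    than aborting the read, unless their fraction exceeds
    ``max_error_fraction``.  Missing columns are fatal.
    """
    path = Path(path)
    report = ReadReport()
    events: list[TraceEvent] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in EXPECTED_COLUMNS if c not in header]
        if missing:
            raise FormatError(
                f"{path}: missing required column(s) {missing}; found {header}"
            )
        for i, row in enumerate(reader, start=2):
            report.n_rows += 1
            try:
                events.append(
                    TraceEvent(
                        actor_id=row["actor_id"].strip(),
                        date=parse_date(row["date"], dialect=dialect),
                        target_action=normalize_token(row["target_action"]),
                    )
                )
            except (ValueError, FormatError, AttributeError, TypeError) as exc:
                report.n_malformed += 1
                report.errors.append(f"line {i}: {exc}")
    report.n_events = len(events)
    if report.n_rows and report.n_malformed / report.n_rows > max_error_fraction:
        raise FormatError(
            f"{path}: {report.n_malformed}/{report.n_rows} rows malformed, "
            f"exceeding the allowed fraction {max_error_fraction}"
        )
    return events, report


def write_trace_log(events: list[TraceEvent], path: str | Path) -> None:
    """Write events as CSV with ISO-8601 dates."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EXPECTED_COLUMNS)
        for ev in events:
            writer.writerow([ev.actor_id, ev.date.isoformat(), ev.target_action])


def assign_weeks(events: list[TraceEvent]) -> list[WeekedEvent]:
    """Map each event's date to its ISO-8601 (year, week); order preserved.

    ISO week numbering is used: e.g. 2019-12-30 belongs to ISO year 2020,
    week 1.
    """
    out = []
    for ev in events:
        iso = ev.date.isocalendar()
        out.append(WeekedEvent(ev.actor_id, iso.year, iso.week, ev.target_action))
    return out


def remove_general_use(
    events: list[WeekedEvent] | list[TraceEvent],
    removal_list: frozenset[str] | set[str] = DEFAULT_REMOVAL_LIST,
) -> tuple[list, Counter]:
    """Drop events whose token is in ``removal_list``.

    Returns the surviving events (order preserved) and a Counter of removed
    events per token.
    """
    removed: Counter = Counter()
    kept = []
    removal = set(removal_list)
    for ev in events:
        if ev.target_action in removal:
            removed[ev.target_action] += 1
        else:
            kept.append(ev)
    return kept, removed


def filter_low_activity_weeks(
    events: list[WeekedEvent],
    min_events: int = DEFAULT_MIN_WEEKLY_EVENTS,
) -> tuple[list[WeekedEvent], dict[tuple[str, int, int], int]]:
    """Drop whole actor-weeks with fewer than ``min_events`` events.

    The threshold is a strict lower bound: an actor-week with exactly
    ``min_events`` events is kept, one with ``min_events - 1`` is dropped.
    Returns surviving events (order preserved) and a dict of dropped
    (actor_id, year, week) -> event count.
    """
    counts: defaultdict[tuple[str, int, int], int] = defaultdict(int)
    for ev in events:
        counts[(ev.actor_id, ev.year, ev.week)] += 1
    dropped = {k: c for k, c in counts.items() if c < min_events}
    kept = [
        ev for ev in events if (ev.actor_id, ev.year, ev.week) not in dropped
    ]
    return kept, dropped


def write_weeked_events(events: list[WeekedEvent], path: str | Path) -> None:
    """Write cleaned events as CSV with ``actor_id,year,week,target_action``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["actor_id", "year", "week", "target_action"])
        for ev in events:
            writer.writerow([ev.actor_id, ev.year, ev.week, ev.target_action])


def read_weeked_events(path: str | Path) -> list[WeekedEvent]:
    """Read cleaned events written by :func:`write_weeked_events`."""
    events = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [
            c
            for c in ("actor_id", "year", "week", "target_action")
            if c not in (reader.fieldnames or [])
        ]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        for row in reader:
            events.append(
                WeekedEvent(
                    row["actor_id"],
                    int(row["year"]),
                    int(row["week"]),
                    normalize_token(row["target_action"]),
                )
            )
    return events
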