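"""All-occurrence-sampling event logs: read, write, per-session streams.

One row per recorded behaviour instance:
``session_id,time_s,actor_id,behaviour_code,group_id`` where ``time_s`` is
seconds from session start (only inter-event gaps matter downstream, so no
wall-clock times are kept). Within a session events are kept time-sorted;
ties preserve file order so downstream chain extraction is deterministic.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import FormatError

logger = logging.getLogger(__name__)

COLUMNS = ("session_id", "time_s", "actor_id", "behaviour_code", "group_id")


@dataclass(frozen=True)
class BehaviouralEvent:
    """One observed behaviour: who did what, when, in which session/group."""

    session_id: str
    time_s: float
    actor_id: str
    behaviour_code: str
    group_id: str = ""

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError(f"time_s must be non-negative, got {self.time_s}")
        if not self.actor_id:
            raise ValueError("actor_id must be non-empty")


@dataclass
class EventLog:
    """An ordered collection of events, indexed per session.

    Events are stored sorted by (session, time) with a stable sort, so the
    multiset of events is conserved and ties keep insertion order.
    """

    events: list[BehaviouralEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.session_id, e.time_s))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[BehaviouralEvent]:
        return iter(self.events)

    @property
    def session_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.events:
            seen.setdefault(e.session_id, None)
        return list(seen)

    def session(self, session_id: str) -> list[BehaviouralEvent]:
        """Time-ordered events of one session."""
        return [e for e in self.events if e.session_id == session_id]

    def sessions(self) -> Iterator[tuple[str, list[BehaviouralEvent]]]:
        for sid in self.session_ids:
            yield sid, self.session(sid)

    @property
    def actor_ids(self) -> list[str]:
        return sorted({e.actor_id for e in self.events})


def read_event_log(path: str | Path) -> EventLog:
    """Read a CSV event log.

    Missing required columns raise :class:`FormatError` naming the column;
    rows with non-numeric or negative times are skipped and logged with their
    row number.
    """
    path = Path(path)
    events: list[BehaviouralEvent] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in COLUMNS if c != "group_id" and c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
        for rownum, row in enumerate(reader, start=2):
            try:
                t = float(row["time_s"])
            except (TypeError, ValueError):
                logger.warning("%s:%d: non-numeric time_s %r; row skipped", path, rownum, row.get("time_s"))
                continue
            try:
                events.append(
                    BehaviouralEvent(
                        session_id=row["session_id"].strip(),
                        time_s=t,
                        actor_id=row["actor_id"].strip(),
                        behaviour_code=row["behaviour_code"].strip(),
                        group_id=(row.get("group_id") or "").strip(),
                    )
                )
            except ValueError as exc:
                logger.warning("%s:%d: %s; row skipped", path, rownum, exc)
    log = EventLog(events)
    return log


def write_event_log(log: EventLog, path: str | Path) -> None:
    """Write a log as CSV; round-trips through :func:`read_event_log`.

    Times are written with millisecond precision (3 decimal places minimum,
    full repr if finer), enough to preserve ordering on re-read.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for e in log.events:
            t = format(e.time_s, ".6f")
            if float(t) != e.time_s:  # fall back to exact repr for odd floats
                t = repr(e.time_s)
            writer.writerow([e.session_id, t, e.actor_id, e.behaviour_code, e.group_id])


def event_log_from_rows(rows: Iterable[tuple]) -> EventLog:
    """Build a log from (session_id, time_s, actor_id, behaviour_code[, group_id]) tuples."""
    events = [BehaviouralEvent(r[0], float(r[1]), r[2], r[3], r[4] if len(r) > 4 else "") for r in rows]
    return EventLog(events)
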