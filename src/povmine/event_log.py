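"""Event logs with day-granularity timestamps.

Clinical information systems often record only the calendar day of an
activity execution, not the time of day. Events of one case that share a
day therefore carry no mutual order information; downstream, the variants
module treats them as parallel. This module covers reading such logs from
CSV and XES, cleaning them (case removal, activity abstraction via a
hierarchy, dropping insignificant activities) and summarising them.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from lxml import etree

#: Column names of the canonical CSV dialect.
DEFAULT_COLUMNS = {
    "case_id": "Case ID",
    "activity": "Activity label",
    "category": "Activity category",
    "timestamp": "Timestamp",
}

#: Day-first date pattern used by the canonical CSV dialect.
DEFAULT_DATE_FORMAT = "%d/%m/%Y"

XES_NS = "http://www.xes-standard.org/"


class EventLogError(ValueError):
    """Configuration or content error while building an event log."""


@dataclass(frozen=True)
class Event:
    """A single activity execution: who (case), what (activity), when (day)."""

    case_id: str
    activity: str
    timestamp: dt.date
    category: str | None = None

    def __post_init__(self) -> None:
        if not self.activity:
            raise EventLogError("event activity label must be non-empty")
        if not isinstance(self.timestamp, dt.date) or isinstance(
            self.timestamp, dt.datetime
        ):
            raise EventLogError("event timestamp must be a datetime.date")


@dataclass(frozen=True)
class Trace:
    """All events of one case, sorted by day; same-day ties keep input order."""

    case_id: str
    events: tuple[Event, ...]

    def __post_init__(self) -> None:
        for e in self.events:
            if e.case_id != self.case_id:
                raise EventLogError(
                    f"event case id {e.case_id!r} differs from trace {self.case_id!r}"
                )
        for a, b in zip(self.events, self.events[1:]):
            if a.timestamp > b.timestamp:
                raise EventLogError("trace events must be non-decreasing in time")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def activities(self) -> tuple[str, ...]:
        return tuple(e.activity for e in self.events)

    @property
    def dates(self) -> tuple[dt.date, ...]:
        return tuple(sorted({e.timestamp for e in self.events}))


@dataclass(frozen=True)
class EventLog:
    """A collection of traces keyed by case id."""

    traces: tuple[Trace, ...]

    def __post_init__(self) -> None:
        ids = [t.case_id for t in self.traces]
        if len(ids) != len(set(ids)):
            raise EventLogError("case ids must be unique within a log")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def __getitem__(self, case_id: str) -> Trace:
        for t in self.traces:
            if t.case_id == case_id:
                return t
        raise KeyError(case_id)

    @property
    def case_ids(self) -> tuple[str, ...]:
        return tuple(t.case_id for t in self.traces)

    @property
    def n_events(self) -> int:
        return sum(len(t) for t in self.traces)

    @property
    def activity_universe(self) -> frozenset[str]:
        return frozenset(e.activity for t in self.traces for e in t.events)


def build_log(events: Iterable[Event]) -> EventLog:
    """Group events by case and sort each case by day (stable for ties)."""
    by_case: dict[str, list[Event]] = {}
    for e in events:
        by_case.setdefault(e.case_id, []).append(e)
    traces = []
    for case_id, evs in by_case.items():
        evs = sorted(evs, key=lambda e: e.timestamp)  # stable: ties keep order
        traces.append(Trace(case_id=case_id, events=tuple(evs)))
    return EventLog(traces=tuple(traces))


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------


def _coerce_date(raw: str, date_format: str, line: int) -> dt.date:
    try:
        parsed = dt.datetime.strptime(raw.strip(), date_format)
    except ValueError as exc:
        raise EventLogError(f"line {line}: unparseable date {raw!r}: {exc}") from exc
    return parsed.date()


def read_event_log(
    path: str | Path,
    format: str = "csv",
    column_map: Mapping[str, str] | None = None,
    date_format: str = DEFAULT_DATE_FORMAT,
    delimiter: str = ",",
) -> EventLog:
    """Read an event log from ``path``.

    Parameters
    ----------
    format
        ``"csv"`` (header row required) or ``"xes"``.
    column_map
        CSV only: maps the logical fields ``case_id``, ``activity``,
        ``timestamp`` and optionally ``category`` to header names. Defaults
        to the canonical dialect (Case ID / Activity label / Activity
        category / Timestamp).
    date_format
        ``strptime`` pattern for CSV timestamps; day-first by default. Any
        time-of-day component is truncated to the date.
    """
    path = Path(path)
    if not path.exists():
        raise EventLogError(f"no such file: {path}")
    if format == "csv":
        return _read_csv(path, column_map or DEFAULT_COLUMNS, date_format, delimiter)
    if format == "xes":
        return _read_xes(path)
    raise EventLogError(f"unknown log format {format!r}")


def _read_csv(
    path: Path, column_map: Mapping[str, str], date_format: str, delimiter: str
) -> EventLog:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for key in ("case_id", "activity", "timestamp"):
            col = column_map.get(key)
            if col is None or col not in header:
                raise EventLogError(
                    f"required column {key!r} (mapped to {col!r}) not in header {header}"
                )
        cat_col = column_map.get("category")
        events = []
        for line_no, row in enumerate(reader, start=2):
            raw_date = row[column_map["timestamp"]]
            category = row.get(cat_col) if cat_col else None
            if category in ("", "-", "–"):
                category = None
            events.append(
                Event(
                    case_id=str(row[column_map["case_id"]]).strip(),
                    activity=row[column_map["activity"]].strip(),
                    timestamp=_coerce_date(raw_date, date_format, line_no),
                    category=category,
                )
            )
    return build_log(events)


def write_event_log(
    log: EventLog,
    path: str | Path,
    format: str = "csv",
    date_format: str = DEFAULT_DATE_FORMAT,
    delimiter: str = ",",
) -> None:
    """Write ``log`` to ``path`` in the canonical CSV dialect or as XES."""
    path = Path(path)
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter=delimiter)
            writer.writerow(
                [
                    DEFAULT_COLUMNS["case_id"],
                    DEFAULT_COLUMNS["activity"],
                    DEFAULT_COLUMNS["category"],
                    DEFAULT_COLUMNS["timestamp"],
                ]
            )
            for trace in log:
                for e in trace.events:
                    writer.writerow(
                        [
                            e.case_id,
                            e.activity,
                            e.category or "-",
                            e.timestamp.strftime(date_format),
                        ]
                    )
    elif format == "xes":
        _write_xes(log, path)
    else:
        raise EventLogError(f"unknown log format {format!r}")


def _read_xes(path: Path) -> EventLog:
    tree = etree.parse(str(path))
    root = tree.getroot()

    def local(tag: str) -> str:
        return etree.QName(tag).localname if "}" in tag else tag

    events: list[Event] = []
    for trace_el in root:
        if local(trace_el.tag) != "trace":
            continue
        case_id = None
        for attr in trace_el:
            if local(attr.tag) == "string" and attr.get("key") == "concept:name":
                case_id = attr.get("value")
        if case_id is None:
            raise EventLogError("XES trace without concept:name")
        for event_el in trace_el:
            if local(event_el.tag) != "event":
                continue
            activity = None
            timestamp = None
            category = None
            for attr in event_el:
                key = attr.get("key")
                if key == "concept:name":
                    activity = attr.get("value")
                elif key == "time:timestamp":
                    timestamp = dt.datetime.fromisoformat(attr.get("value")).date()
                elif key == "category":
                    category = attr.get("value")
            if activity is None or timestamp is None:
                raise EventLogError(
                    f"XES event in trace {case_id!r} lacks concept:name or time:timestamp"
                )
            events.append(
                Event(
                    case_id=case_id,
                    activity=activity,
                    timestamp=timestamp,
                    category=category,
                )
            )
    return build_log(events)


def _write_xes(log: EventLog, path: Path) -> None:
    root = etree.Element("log", nsmap={None: XES_NS})
    for trace in log:
        trace_el = etree.SubElement(root, "trace")
        etree.SubElement(
            trace_el, "string", key="concept:name", value=trace.case_id
        )
        for e in trace.events:
            event_el = etree.SubElement(trace_el, "event")
            etree.SubElement(
                event_el, "string", key="concept:name", value=e.activity
            )
            if e.category:
                etree.SubElement(
                    event_el, "string", key="category", value=e.category
                )
            etree.SubElement(
                event_el,
                "date",
                key="time:timestamp",
                value=e.timestamp.isoformat() + "T00:00:00",
            )
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# ---------------------------------------------------------------------------
# Activity hierarchy / abstraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivityHierarchy:
    """Low-level to abstract label mapping, with a drop set.

    Multi-level abstraction is expressed by chained entries
    (``CT abdomen -> CT scan``, ``CT scan -> Imaging``); chains are resolved
    transitively when the hierarchy is constructed, so application is a
    single relabeling pass and idempotent.
    """

    mapping: Mapping[str, str] = field(default_factory=dict)
    drop: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "mapping", dict(self.mapping))
        object.__setattr__(self, "drop", frozenset(self.drop))
        object.__setattr__(self, "_resolved", self._resolve())

    def _resolve(self) -> dict[str, str]:
        resolved: dict[str, str] = {}
        for source in self.mapping:
            seen = [source]
            label = source
            while label in self.mapping:
                label = self.mapping[label]
                if label in seen:
                    cycle = " -> ".join(seen + [label])
                    raise EventLogError(f"cyclic activity hierarchy: {cycle}")
                seen.append(label)
            resolved[source] = label
        return resolved

    def resolve(self, label: str) -> str:
        return self._resolved.get(label, label)

    @classmethod
    def from_dict(cls, config: Mapping) -> "ActivityHierarchy":
        return cls(
            mapping=dict(config.get("mapping", {})),
            drop=frozenset(config.get("drop", [])),
        )


def relabel_activities(log: EventLog, hierarchy: ActivityHierarchy) -> EventLog:
    """Abstract activities per the hierarchy; event count is conserved."""
    events = [
        Event(
            case_id=e.case_id,
            activity=hierarchy.resolve(e.activity),
            timestamp=e.timestamp,
            category=e.category,
        )
        for t in log
        for e in t.events
    ]
    return build_log(events)


def drop_activities(log: EventLog, labels: Iterable[str]) -> EventLog:
    """Remove all events whose label is in ``labels``; emptied cases vanish."""
    labels = frozenset(labels)
    events = [e for t in log for e in t.events if e.activity not in labels]
    return build_log(events)


def remove_cases(log: EventLog, keep: Callable[[Trace], bool]) -> EventLog:
    """Keep exactly the traces for which ``keep`` is true; others are removed."""
    return EventLog(traces=tuple(t for t in log if keep(t)))


def log_summary(log: EventLog) -> dict:
    """Counts of cases, events, distinct activities and distinct variants."""
    from . import variants as _variants

    return {
        "cases": len(log),
        "events": log.n_events,
        "activities": len(log.activity_universe),
        "variants": len(_variants.variant_table(log)),
    }
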