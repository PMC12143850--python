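"""The traffic-light behavioral observation log.

Staff, teachers and research observers record agitated or aggressive behavior
with a clock time, a free-text description and a color code:

* green  — good behavior (e.g. receiving a compliment for correct behavior);
* orange — disruptive behavior;
* red    — physical aggression and severe disruptive behavior.

Colors are an *input*: no attempt is made to re-code descriptions.  Times are
at minute resolution (observers wrote clock times); every event carries an
uncertainty half-width used only for window-overlap tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from zoneinfo import ZoneInfo

import pandas as pd

__all__ = [
    "COLORS",
    "COLOR_MEANING",
    "ObservationEvent",
    "ObservationLog",
    "read_observations",
    "write_observations",
    "tally",
]

COLORS = ("green", "orange", "red")

#: the traffic-light coding schema used in the daycare and clinic
COLOR_MEANING = {
    "green": "Good behavior",
    "orange": "Disruptive behavior",
    "red": "Physical aggression and severe disruptive behavior",
}

#: colors counting as aggression observations
AGGRESSION_COLORS = ("orange", "red")

CSV_COLUMNS = ["participant_id", "local_datetime", "color", "description", "observer"]
OBSERVERS = ("staff", "researcher", "teacher")
DT_FORMAT = "%Y-%m-%d %H:%M"


@dataclass
class ObservationEvent:
    participant_id: str
    timestamp: float  # UTC seconds
    color: str
    description: str = ""
    observer: str = "staff"
    uncertainty_s: float = 60.0  # timestamping half-width for overlap tests

    def __post_init__(self) -> None:
        if self.color not in COLORS:
            raise ValueError(f"unknown color {self.color!r}")

    def interval(self) -> tuple[float, float]:
        """The event's time interval under its timestamp uncertainty."""
        return (self.timestamp - self.uncertainty_s, self.timestamp + self.uncertainty_s)

    def overlaps(self, start: float, end: float) -> bool:
        lo, hi = self.interval()
        return hi > start and lo < end


@dataclass
class ObservationLog:
    """Time-ordered (within participant) sequence of observation events."""

    events: list[ObservationEvent] = field(default_factory=list)
    row_errors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.participant_id, e.timestamp))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def for_participant(self, pid: str, colors=None) -> list[ObservationEvent]:
        return [
            e
            for e in self.events
            if e.participant_id == pid and (colors is None or e.color in colors)
        ]

    def dedupe(self) -> "ObservationLog":
        """Drop exact duplicate rows (explicit opt-in; double reports by two
        observer streams are legitimate and kept by default)."""
        seen: set[tuple] = set()
        kept = []
        for e in self.events:
            key = (e.participant_id, e.timestamp, e.color, e.description, e.observer)
            if key not in seen:
                seen.add(key)
                kept.append(e)
        return ObservationLog(kept)


def read_observations(path: str | Path, timezone: str = "UTC") -> ObservationLog:
    """Parse an observation CSV; bad rows are skipped with a per-line report.

    Unknown colors and unparseable datetimes are rejected row-wise: each
    rejection is recorded (with its line number) on ``log.row_errors`` and
    emitted as a warning.  Exact duplicate rows are kept with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing and len(df.columns) and not df.empty:
        raise ValueError(f"observation CSV missing columns: {missing}")
    tz = ZoneInfo(timezone)
    events: list[ObservationEvent] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        color = str(row.get("color", "")).strip().lower()
        if color not in COLORS:
            errors.append(f"line {line}: unknown color {row.get('color')!r}")
            continue
        try:
            dt = datetime.strptime(str(row["local_datetime"]).strip(), DT_FORMAT)
        except ValueError:
            errors.append(f"line {line}: unparseable datetime {row.get('local_datetime')!r}")
            continue
        events.append(
            ObservationEvent(
                participant_id=str(row["participant_id"]).strip(),
                timestamp=dt.replace(tzinfo=tz).timestamp(),
                color=color,
                description=str(row.get("description", "")),
                observer=str(row.get("observer", "staff")) or "staff",
            )
        )
    for err in errors:
        warnings.warn(f"{path.name}: {err}")
    log = ObservationLog(events, row_errors=errors)
    n_dupes = len(log.events) - len(log.dedupe().events)
    if n_dupes:
        warnings.warn(f"{path.name}: {n_dupes} exact duplicate row(s) kept")
    return log


def write_observations(log: ObservationLog, path: str | Path, timezone: str = "UTC") -> None:
    tz = ZoneInfo(timezone)
    rows = [
        {
            "participant_id": e.participant_id,
            "local_datetime": datetime.fromtimestamp(e.timestamp, tz).strftime(DT_FORMAT),
            "color": e.color,
            "description": e.description,
            "observer": e.observer,
        }
        for e in log.events
    ]
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def tally(log: ObservationLog) -> dict:
    """Event and unique-participant counts per color, plus the aggression total.

    Green events are excluded from the aggression total; duplicates count
    twice (deduplication is an explicit, separate step).
    """
    out: dict = {}
    for color in COLORS:
        evs = [e for e in log.events if e.color == color]
        out[color] = {
            "events": len(evs),
            "participants": len({e.participant_id for e in evs}),
        }
    out["aggression_total"] = sum(out[c]["events"] for c in AGGRESSION_COLORS)
    return out
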