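"""Camera-trap detections to independent activity events and daily counts.

A camera fires repeatedly while an animal forages, so raw detections are
collapsed into independent events with a 30-minute rule: a detection whose gap
to the previous detection is under the window joins the running event, a gap
of the window or more opens a new one.  Events are dated by their start
timestamp, summed into per-beach daily counts (with malfunction days
excluded), and optionally classified into day / twilight / night from a
user-supplied sun table.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SPECIES",
    "Detection",
    "ActivityEvent",
    "collapse_detections",
    "daily_activity",
    "diel_profile",
]

SPECIES = ("black_bear", "gray_wolf", "deer", "cougar", "other")

DEFAULT_WINDOW_MINUTES = 30.0


@dataclass(frozen=True)
class Detection:
    """One timestamped camera record (minute precision).

    A female with cubs is a single detection: group size never inflates
    counts.
    """

    beach_id: str
    species: str
    timestamp: datetime
    group_note: str = ""

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}; expected one of {SPECIES}")


@dataclass(frozen=True)
class ActivityEvent:
    """A run of detections collapsed into one independent visit."""

    beach_id: str
    species: str
    start: datetime
    end: datetime
    n_detections: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("event end precedes start")
        if self.n_detections < 1:
            raise ValueError("event must contain at least one detection")


def collapse_detections(
    detections: Iterable[Detection],
    window_minutes: float = DEFAULT_WINDOW_MINUTES,
    *,
    anchor: str = "previous",
) -> list[ActivityEvent]:
    """Collapse one beach-and-species detection stream into independent events.

    With ``anchor="previous"`` (the default) each detection is compared to the
    immediately preceding detection: gaps strictly under ``window_minutes``
    chain, gaps of the window or more split.  ``anchor="first"`` instead
    measures every gap from the event's first detection, a stricter windowed
    variant exposed for sensitivity analysis.

    Detections may arrive unsorted; they are ordered by timestamp first.
    Mixed beaches or species in one stream are rejected — collapse per
    beach-species group (see :func:`daily_activity` callers).
    """
    if anchor not in ("previous", "first"):
        raise ValueError("anchor must be 'previous' or 'first'")
    dets = sorted(detections, key=lambda d: d.timestamp)
    if not dets:
        return []
    keys = {(d.beach_id, d.species) for d in dets}
    if len(keys) > 1:
        raise ValueError(f"stream mixes beach/species groups: {sorted(keys)}")

    window = timedelta(minutes=window_minutes)
    events: list[ActivityEvent] = []
    run: list[Detection] = [dets[0]]
    for det in dets[1:]:
        ref = run[0].timestamp if anchor == "first" else run[-1].timestamp
        if det.timestamp - ref < window:
            run.append(det)
        else:
            events.append(_make_event(run))
            run = [det]
    events.append(_make_event(run))
    return events


def _make_event(run: Sequence[Detection]) -> ActivityEvent:
    return ActivityEvent(
        beach_id=run[0].beach_id,
        species=run[0].species,
        start=run[0].timestamp,
        end=run[-1].timestamp,
        n_detections=len(run),
    )


def daily_activity(
    events: Iterable[ActivityEvent],
    calendar: pd.DataFrame,
    *,
    species: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per beach x date x species independent-event counts on operational days.

    ``calendar`` needs columns ``beach_id``, ``date``, ``operational`` (0/1)
    and must cover every event date; an event on a non-operational day means
    the inputs disagree and raises.  Operational days with no events get
    explicit zero rows so downstream models see true absences.  Events are
    assigned to the date of their start timestamp.

    Wolf (and other non-bear) events are counted exactly like bear events:
    one count per independent event, regardless of group size.
    """
    cal = calendar.copy()
    cal["date"] = pd.to_datetime(cal["date"]).dt.date
    cal["operational"] = cal["operational"].astype(bool)
    op_index = set(zip(cal["beach_id"], cal["date"]))
    valid = {
        (b, d) for b, d, op in zip(cal["beach_id"], cal["date"], cal["operational"]) if op
    }

    events = list(events)
    species_list = list(species) if species is not None else sorted({e.species for e in events})

    counts: dict[tuple[str, date, str], int] = {}
    for ev in events:
        ev_date = ev.start.date()
        key = (ev.beach_id, ev_date)
        if key not in op_index:
            raise ValueError(
                f"event on {ev.beach_id} at {ev.start} outside the operational calendar"
            )
        if key not in valid:
            raise ValueError(
                f"event on {ev.beach_id} at {ev.start} falls on a non-operational day"
            )
        counts[(ev.beach_id, ev_date, ev.species)] = (
            counts.get((ev.beach_id, ev_date, ev.species), 0) + 1
        )

    rows = [
        {
            "beach_id": b,
            "date": d,
            "species": sp,
            "count": counts.get((b, d, sp), 0),
        }
        for (b, d) in sorted(valid)
        for sp in species_list
    ]
    return pd.DataFrame(rows, columns=["beach_id", "date", "species", "count"])


def _parse_time(value) -> time:
    if isinstance(value, time):
        return value
    if isinstance(value, datetime):
        return value.time()
    return datetime.strptime(str(value), "%H:%M").time()


def diel_profile(
    events: Iterable[ActivityEvent],
    sun_table: pd.DataFrame | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Event counts by hour of day and, given a sun table, by light class.

    The sun table carries per-date local times ``nautical_dawn``, ``sunrise``,
    ``sunset``, ``nautical_dusk``.  An event is classified by its start:
    ``day`` on [sunrise, sunset), ``twilight`` on [nautical_dawn, sunrise) or
    [sunset, nautical_dusk) — the union of civil and nautical twilight — and
    ``night`` otherwise, so a start exactly at sunset is twilight.  Missing
    dates raise.
    """
    events = list(events)
    hour_counts = pd.Series(0, index=range(24), name="events")
    for ev in events:
        hour_counts[ev.start.hour] += 1

    light_counts = pd.Series(0, index=["day", "twilight", "night"], name="events")
    if sun_table is not None:
        sun = sun_table.copy()
        sun["date"] = pd.to_datetime(sun["date"]).dt.date
        sun = sun.set_index("date")
        for ev in events:
            ev_date = ev.start.date()
            if ev_date not in sun.index:
                raise ValueError(f"sun table has no entry for {ev_date}")
            row = sun.loc[ev_date]
            t = ev.start.time()
            dawn = _parse_time(row["nautical_dawn"])
            sunrise = _parse_time(row["sunrise"])
            sunset = _parse_time(row["sunset"])
            dusk = _parse_time(row["nautical_dusk"])
            if sunrise <= t < sunset:
                light_counts["day"] += 1
            elif dawn <= t < sunrise or sunset <= t < dusk:
                light_counts["twilight"] += 1
            else:
                light_counts["night"] += 1
    return hour_counts, light_counts
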