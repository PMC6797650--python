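"""Containers and I/O for dyadic face-to-face contact event logs.

A contact event is one undirected dyadic interaction interval, recorded
either by a pair of worn proximity badges or by a human coder watching
video of the same scene.  Both sources share the same four-column record:
start time, badge/person A, badge/person B, end time.

Internally all times are integer seconds from an observation origin and
intervals are half-open, ``[start, end)``: durations are additive and an
event ending at *t* abuts (and merges with) one starting at *t*, which is
the right behaviour at 1-second resolution where a zero-length gap is
indistinguishable from a continuous signal.

The central derived structure is the :class:`DyadRaster` — one row per
unordered dyad, one column per second, entries 0/1 for "interaction
present at this second".  All validity metrics downstream are computed on
this dyad-second grid.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ContactDataError",
    "ParseError",
    "ValidationError",
    "ConfigError",
    "ContactEvent",
    "EventLog",
    "DyadRaster",
    "LogSummary",
    "canonical_dyad",
    "read_event_log",
    "write_event_log",
    "rasterize",
    "events_from_raster",
    "aggregate_minutes",
    "summarize",
    "write_graphml",
]

Ident = Union[int, str]


class ContactDataError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(ContactDataError):
    """An input file could not be parsed."""


class ValidationError(ContactDataError):
    """Data violate an event-log invariant or operation precondition."""


class ConfigError(ContactDataError):
    """A configuration value or structure is invalid."""


def _ident_key(ident: Ident):
    # Integer identifiers sort numerically before everything else; other
    # identifiers sort lexically.  Gives a total order on mixed rosters.
    if isinstance(ident, (int, np.integer)):
        return (0, int(ident), "")
    return (1, 0, str(ident))


def canonical_dyad(a: Ident, b: Ident) -> tuple[Ident, Ident]:
    """Return the unordered pair ``{a, b}`` in canonical (sorted) order."""
    if _ident_key(a) <= _ident_key(b):
        return (a, b)
    return (b, a)


@dataclass(frozen=True)
class ContactEvent:
    """One undirected dyadic interaction interval ``[start, end)`` in seconds."""

    id_a: Ident
    id_b: Ident
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValidationError(f"self-contact not allowed: id_a = id_b = {self.id_a!r}")
        start, end = int(self.start), int(self.end)
        if end <= start:
            raise ValidationError(f"event end must be after start: [{start}, {end})")
        a, b = canonical_dyad(self.id_a, self.id_b)
        object.__setattr__(self, "id_a", a)
        object.__setattr__(self, "id_b", b)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)

    @property
    def dyad(self) -> tuple[Ident, Ident]:
        return (self.id_a, self.id_b)

    @property
    def duration(self) -> int:
        """Duration in seconds (``end - start``)."""
        return self.end - self.start


class EventLog:
    """A normalized, windowed collection of :class:`ContactEvent`.

    Normalization guarantees: dyads stored canonically; events sorted by
    (start, dyad); same-dyad events that overlap or abut are merged, so
    consecutive events of one dyad are separated by at least 1 s.

    Parameters
    ----------
    events
        Any iterable of :class:`ContactEvent` (merged and sorted on entry).
    roster
        Participant identifiers.  Defaults to the identifiers appearing in
        ``events``; may be larger (silent participants count for dyad
        bookkeeping).
    window
        Half-open observation interval ``[t0, t1)`` in seconds.  Defaults
        to ``[min start, max end)`` over the events.
    """

    def __init__(
        self,
        events: Iterable[ContactEvent] = (),
        roster: Iterable[Ident] | None = None,
        window: tuple[int, int] | None = None,
    ) -> None:
        merged = self._normalize(events)
        if window is None:
            if merged:
                window = (merged[0].start, max(e.end for e in merged))
            else:
                window = (0, 0)
        t0, t1 = int(window[0]), int(window[1])
        if t1 < t0:
            raise ValidationError(f"window end before start: [{t0}, {t1})")
        for e in merged:
            if e.start < t0 or e.end > t1:
                raise ValidationError(
                    f"event [{e.start}, {e.end}) of dyad {e.dyad} outside window [{t0}, {t1})"
                )
        ids = {i for e in merged for i in e.dyad}
        if roster is None:
            roster_set = frozenset(ids)
        else:
            roster_set = frozenset(roster)
            if not ids <= roster_set:
                raise ValidationError(f"events involve identifiers outside roster: {ids - roster_set}")
        self.events: tuple[ContactEvent, ...] = tuple(merged)
        self.roster: frozenset = roster_set
        self.window: tuple[int, int] = (t0, t1)

    @staticmethod
    def _normalize(events: Iterable[ContactEvent]) -> list[ContactEvent]:
        by_dyad: dict[tuple, list[ContactEvent]] = {}
        for e in events:
            by_dyad.setdefault(e.dyad, []).append(e)
        out: list[ContactEvent] = []
        for dyad, evs in by_dyad.items():
            evs.sort(key=lambda e: e.start)
            cur_start, cur_end = evs[0].start, evs[0].end
            for e in evs[1:]:
                if e.start <= cur_end:  # overlap or abut -> merge
                    cur_end = max(cur_end, e.end)
                else:
                    out.append(ContactEvent(dyad[0], dyad[1], cur_start, cur_end))
                    cur_start, cur_end = e.start, e.end
            out.append(ContactEvent(dyad[0], dyad[1], cur_start, cur_end))
        out.sort(key=lambda e: (e.start, _ident_key(e.id_a), _ident_key(e.id_b)))
        return out

    # -- derived quantities -------------------------------------------------

    def sorted_roster(self) -> list[Ident]:
        return sorted(self.roster, key=_ident_key)

    def dyads(self) -> list[tuple[Ident, Ident]]:
        """All unordered roster pairs in canonical order (D = N(N-1)/2)."""
        return list(itertools.combinations(self.sorted_roster(), 2))

    @property
    def n_participants(self) -> int:
        return len(self.roster)

    @property
    def n_dyads(self) -> int:
        n = len(self.roster)
        return n * (n - 1) // 2

    @property
    def window_length(self) -> int:
        """Observation length S in seconds."""
        return self.window[1] - self.window[0]

    def total_contact_seconds(self) -> int:
        return sum(e.duration for e in self.events)

    def restricted(self, t0: int, t1: int) -> "EventLog":
        """Events clipped to ``[t0, t1)`` (sub-window of the current window)."""
        if t0 < self.window[0] or t1 > self.window[1] or t1 < t0:
            raise ValidationError(f"[{t0}, {t1}) is not a sub-window of {self.window}")
        clipped = [
            ContactEvent(e.id_a, e.id_b, max(e.start, t0), min(e.end, t1))
            for e in self.events
            if max(e.start, t0) < min(e.end, t1)
        ]
        return EventLog(clipped, roster=self.roster, window=(t0, t1))

    def with_window(self, window: tuple[int, int]) -> "EventLog":
        return EventLog(self.events, roster=self.roster, window=window)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start": [e.start for e in self.events],
                "id_a": [e.id_a for e in self.events],
                "id_b": [e.id_b for e in self.events],
                "end": [e.end for e in self.events],
            }
        )

    def __len__(self) -> int:
        return len(self.events)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventLog):
            return NotImplemented
        return (
            self.events == other.events
            and self.roster == other.roster
            and self.window == other.window
        )

    def __repr__(self) -> str:
        return (
            f"EventLog({len(self.events)} events, {len(self.roster)} participants, "
            f"window=[{self.window[0]}, {self.window[1]}))"
        )


@dataclass
class DyadRaster:
    """Dyads x seconds binary presence matrix (the linear time dimension).

    ``data[d, i]`` is 1 iff second ``t0 + i`` is covered by an event of the
    d-th dyad.  Rows follow :meth:`EventLog.dyads` order and include every
    roster dyad, active or not, so the shape is exactly D x S.
    """

    data: np.ndarray
    dyads: list[tuple[Ident, Ident]]
    t0: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.dyads):
            raise ValidationError(
                f"raster shape {self.data.shape} does not match {len(self.dyads)} dyads"
            )
        self._index = {d: k for k, d in enumerate(self.dyads)}

    @property
    def n_dyads(self) -> int:
        return self.data.shape[0]

    @property
    def n_seconds(self) -> int:
        return self.data.shape[1]

    def row(self, a: Ident, b: Ident) -> np.ndarray:
        return self.data[self._index[canonical_dyad(a, b)]]

    def active_seconds(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class LogSummary:
    """Descriptive statistics of an event log.

    Event-level durations are in seconds; dyad-level and individual-level
    totals are in minutes.  Individual totals count each event for both
    participants, so the grand individual total is twice the summed event
    time.  Moments use the sample (n-1) standard deviation and are NaN
    when undefined.
    """

    n_events: int
    duration_mean_s: float
    duration_sd_s: float
    dyadic_minutes_mean: float
    dyadic_minutes_sd: float
    individual_minutes_mean: float
    individual_minutes_sd: float

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "duration_mean_s": self.duration_mean_s,
            "duration_sd_s": self.duration_sd_s,
            "dyadic_minutes_mean": self.dyadic_minutes_mean,
            "dyadic_minutes_sd": self.dyadic_minutes_sd,
            "individual_minutes_mean": self.individual_minutes_mean,
            "individual_minutes_sd": self.individual_minutes_sd,
        }


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("start", "id_a", "id_b", "end")


def _parse_ident(text: str) -> Ident:
    text = text.strip()
    if text.lstrip("-").isdigit():
        return int(text)
    return text


def _detect_dialect(sample: str) -> str:
    sample = sample.strip()
    if "T" in sample or "-" in sample[1:]:
        return "iso"
    if ":" in sample:
        return "clock"
    return "seconds"


def _parse_clock(text: str) -> int:
    parts = text.strip().split(":")
    if len(parts) != 3:
        raise ValueError(f"clock time must be HH:MM:SS, got {text!r}")
    h, m, s = (int(p) for p in parts)
    if not (0 <= h < 24 and 0 <= m < 60 and 0 <= s < 60):
        raise ValueError(f"clock time out of range: {text!r}")
    return h * 3600 + m * 60 + s


def read_event_log(
    source: Union[str, Path, IO[str]],
    dialect: str = "auto",
    roster: Iterable[Ident] | None = None,
    window: tuple[int, int] | None = None,
) -> EventLog:
    """Read and normalize a contact event log from CSV.

    Expects a header with columns ``start, id_a, id_b, end``.  Times may be
    integer seconds, clock times ``HH:MM:SS`` (interpreted within a single
    day; records apparently crossing midnight are rejected — use
    date-stamped ISO times for multi-day collections), or ISO timestamps
    ``YYYY-MM-DDTHH:MM:SS`` (converted to seconds from midnight of the
    earliest date).  ``dialect`` may force one of ``seconds``, ``clock``,
    ``iso`` instead of auto-detection.
    """
    try:
        df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    except Exception as exc:  # pragma: no cover - delegated to pandas
        raise ParseError(f"could not read CSV: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns: {missing} (have {list(df.columns)})")
    if len(df) == 0:
        return EventLog([], roster=roster, window=window)

    if dialect == "auto":
        dialect = _detect_dialect(str(df["start"].iloc[0]))
    if dialect not in ("seconds", "clock", "iso"):
        raise ConfigError(f"unknown time dialect {dialect!r}")

    starts: list = []
    ends: list = []
    for lineno, (raw_s, raw_e) in enumerate(zip(df["start"], df["end"]), start=2):
        try:
            if dialect == "seconds":
                starts.append(int(str(raw_s).strip()))
                ends.append(int(str(raw_e).strip()))
            elif dialect == "clock":
                starts.append(_parse_clock(str(raw_s)))
                ends.append(_parse_clock(str(raw_e)))
            else:
                starts.append(pd.Timestamp(str(raw_s).strip()))
                ends.append(pd.Timestamp(str(raw_e).strip()))
        except (ValueError, TypeError) as exc:
            raise ParseError(f"line {lineno}: malformed time ({exc})") from exc
    if dialect == "iso":
        origin = min(starts).normalize()
        starts = [int((t - origin).total_seconds()) for t in starts]
        ends = [int((t - origin).total_seconds()) for t in ends]

    events = []
    for lineno, (s, a, b, e) in enumerate(zip(starts, df["id_a"], df["id_b"], ends), start=2):
        if pd.isna(a) or pd.isna(b):
            raise ParseError(f"line {lineno}: missing identifier")
        if dialect == "clock" and e < s:
            raise ValidationError(
                f"line {lineno}: end clock time precedes start — events crossing "
                "midnight require date-stamped (ISO) input"
            )
        try:
            events.append(ContactEvent(_parse_ident(str(a)), _parse_ident(str(b)), s, e))
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from exc
    return EventLog(events, roster=roster, window=window)


def write_event_log(log: EventLog, destination: Union[str, Path, IO[str]]) -> None:
    """Write a log as CSV with header ``start,id_a,id_b,end`` (integer seconds).

    Round trip contract: ``read_event_log(write_event_log(log))`` restores
    ``log`` exactly when roster and window are implied by the events.
    """
    log.to_frame().to_csv(destination, index=False)


# ---------------------------------------------------------------------------
# rasterization and aggregation
# ---------------------------------------------------------------------------

def rasterize(log: EventLog) -> DyadRaster:
    """Binary dyad x second presence matrix over the log's roster and window."""
    if len(log.roster) < 2:
        raise ValidationError(f"rasterization needs >= 2 participants, got {len(log.roster)}")
    dyads = log.dyads()
    t0, t1 = log.window
    data = np.zeros((len(dyads), t1 - t0), dtype=bool)
    index = {d: k for k, d in enumerate(dyads)}
    for e in log.events:
        data[index[e.dyad], e.start - t0 : e.end - t0] = True
    return DyadRaster(data, dyads, t0)


def events_from_raster(raster: DyadRaster, roster: Iterable[Ident] | None = None) -> EventLog:
    """Inverse of :func:`rasterize`: maximal runs of ones become events."""
    if roster is None:
        roster = {i for d in raster.dyads for i in d}
    events = []
    for (a, b), row in zip(raster.dyads, raster.data):
        padded = np.diff(np.concatenate(([0], row.astype(np.int8), [0])))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        for s, e in zip(starts, ends):
            events.append(ContactEvent(a, b, raster.t0 + int(s), raster.t0 + int(e)))
    return EventLog(events, roster=roster, window=(raster.t0, raster.t0 + raster.n_seconds))


def aggregate_minutes(log: EventLog) -> pd.DataFrame:
    """Symmetric roster x roster matrix of interaction minutes, zero diagonal.

    Entry (i, j) is the summed duration of all {i, j} events divided by 60
    (Study-2-style weighted contact matrix).
    """
    ids = log.sorted_roster()
    x = pd.DataFrame(0.0, index=ids, columns=ids)
    for e in log.events:
        x.loc[e.id_a, e.id_b] += e.duration / 60.0
        x.loc[e.id_b, e.id_a] += e.duration / 60.0
    return x


def _sample_stats(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return (math.nan, math.nan)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else math.nan
    return mean, sd


def summarize(log: EventLog, include_zero_dyads: bool = False) -> LogSummary:
    """Descriptive statistics of a log.

    ``dyadic_minutes_*`` are over dyads with nonzero aggregated contact
    time by default (``include_zero_dyads=True`` averages over all roster
    dyads instead).  Individual totals are over all roster members.
    """
    durations = [e.duration for e in log.events]
    dur_mean, dur_sd = _sample_stats(durations)

    dyad_minutes: dict[tuple, float] = {}
    indiv_minutes: dict[Ident, float] = {i: 0.0 for i in log.roster}
    for e in log.events:
        dyad_minutes[e.dyad] = dyad_minutes.get(e.dyad, 0.0) + e.duration / 60.0
        indiv_minutes[e.id_a] += e.duration / 60.0
        indiv_minutes[e.id_b] += e.duration / 60.0
    if include_zero_dyads:
        values = [dyad_minutes.get(d, 0.0) for d in log.dyads()]
    else:
        values = list(dyad_minutes.values())
    dyad_mean, dyad_sd = _sample_stats(values)
    ind_mean, ind_sd = _sample_stats(list(indiv_minutes.values())) if log.roster else (math.nan, math.nan)

    return LogSummary(
        n_events=len(log.events),
        duration_mean_s=dur_mean,
        duration_sd_s=dur_sd,
        dyadic_minutes_mean=dyad_mean,
        dyadic_minutes_sd=dyad_sd,
        individual_minutes_mean=ind_mean,
        individual_minutes_sd=ind_sd,
    )


def write_graphml(log: EventLog, path: Union[str, Path]) -> None:
    """Export the aggregated weighted contact network as GraphML."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(str(i) for i in log.sorted_roster())
    x = aggregate_minutes(log)
    for (a, b) in log.dyads():
        w = float(x.loc[a, b])
        if w > 0:
            g.add_edge(str(a), str(b), minutes=w)
    nx.write_graphml(g, path)
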