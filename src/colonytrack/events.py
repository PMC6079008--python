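"""Detection-event ingest and movement reconstruction.

The single source of truth for the whole pipeline is the detection event
stream: one row per RFID/infrared detection, with millisecond-precision
timestamps, an animal tag, a sensor id and a sensor kind.  This module
parses and validates such streams, reconstructs per-mouse compartment
transitions from tube-antenna detection pairs, derives compartment visits,
and annotates timestamped records with experimental sessions.

Conventions
-----------
* Timestamps are integer milliseconds since a configurable experiment
  epoch.
* All intervals are half-open ``[start, end)``; a boundary instant belongs
  to the later interval, so intervals partition time without double
  counting.
* Events are totally ordered by ``(timestamp, sensor_id, mouse_id)`` so
  that simultaneous detections have a deterministic order.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SENSOR_KINDS",
    "EventLogError",
    "TopologyError",
    "ScheduleError",
    "EventLog",
    "Tube",
    "Topology",
    "SessionSchedule",
    "AnomalyReport",
    "read_event_log",
    "write_event_log",
    "reconstruct_transitions",
    "build_visits",
    "assign_sessions",
    "split_visits_by_session",
]

SENSOR_KINDS = ("tube_antenna", "floor_antenna", "gate", "beam")

#: canonical column order of an event log
EVENT_COLUMNS = ["timestamp", "mouse_id", "sensor_id", "sensor_kind", "extra"]

#: canonical column order of a transition table
TRANSITION_COLUMNS = ["mouse_id", "from_compartment", "to_compartment", "t_start", "t_end"]

#: canonical column order of a visit table
VISIT_COLUMNS = ["mouse_id", "compartment", "t_enter", "t_exit"]


class EventLogError(ValueError):
    """Raised when an event log fails validation."""


class TopologyError(ValueError):
    """Raised when an environment topology is inconsistent."""


class ScheduleError(ValueError):
    """Raised when a session schedule is malformed (overlap, disorder)."""


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Tube:
    """A connecting tube with one RFID antenna at each end.

    ``antenna_a`` sits on the ``compartment_a`` side, so the detection
    order (a then b) determines the direction of a crossing.
    """

    antenna_a: str
    antenna_b: str
    compartment_a: str
    compartment_b: str


@dataclass
class Topology:
    """The compartment graph of the environment.

    Parameters
    ----------
    compartments
        Names of the sub-compartments (e.g. NC nest, FC food, CC central,
        St stairs, T test zone); arbitrary user-defined names are allowed.
    tubes
        Tubes connecting compartments, each with its antenna pair.
    floor_antennas
        Mapping of floor-antenna sensor id to the compartment it covers.
    gate
        Sensor id of the gate between the social cage and the test zone,
        or ``None`` if the environment has no gate.
    beams
        Mapping of infrared-beam sensor id to the maze arm ("L"/"R").
    """

    compartments: tuple[str, ...]
    tubes: tuple[Tube, ...] = ()
    floor_antennas: Mapping[str, str] = field(default_factory=dict)
    gate: str | None = None
    beams: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.compartments = tuple(self.compartments)
        self.tubes = tuple(
            t if isinstance(t, Tube) else Tube(*t) for t in self.tubes
        )
        comps = set(self.compartments)
        seen: Counter[str] = Counter()
        for t in self.tubes:
            if t.antenna_a == t.antenna_b:
                raise TopologyError(f"tube has identical antennas: {t}")
            seen[t.antenna_a] += 1
            seen[t.antenna_b] += 1
            for c in (t.compartment_a, t.compartment_b):
                if c not in comps:
                    raise TopologyError(f"tube references unknown compartment {c!r}")
        dup = [a for a, n in seen.items() if n > 1]
        if dup:
            raise TopologyError(f"antennas shared between tubes: {sorted(dup)}")
        for ant, c in self.floor_antennas.items():
            if c not in comps:
                raise TopologyError(
                    f"floor antenna {ant!r} maps to unknown compartment {c!r}"
                )
        if self.tubes and not self._connected():
            raise TopologyError("compartment graph is not connected")
        # antenna -> (tube, side) lookup
        self._tube_of: dict[str, tuple[Tube, str]] = {}
        for t in self.tubes:
            self._tube_of[t.antenna_a] = (t, "a")
            self._tube_of[t.antenna_b] = (t, "b")

    def _connected(self) -> bool:
        adj: dict[str, set[str]] = {c: set() for c in self.compartments}
        for t in self.tubes:
            adj[t.compartment_a].add(t.compartment_b)
            adj[t.compartment_b].add(t.compartment_a)
        if self.gate is not None and {"St", "T"} <= set(self.compartments):
            adj["St"].add("T")
            adj["T"].add("St")
        start = self.compartments[0]
        stack, seen = [start], {start}
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return seen == set(self.compartments)

    # -- lookups ----------------------------------------------------------

    @property
    def tube_antennas(self) -> set[str]:
        return set(self._tube_of)

    @property
    def sensor_ids(self) -> set[str]:
        ids = self.tube_antennas | set(self.floor_antennas) | set(self.beams)
        if self.gate is not None:
            ids.add(self.gate)
        return ids

    def tube_for_antenna(self, antenna: str) -> tuple[Tube, str]:
        """Return the tube containing ``antenna`` and which side ('a'/'b')."""
        return self._tube_of[antenna]

    def edges(self) -> set[frozenset[str]]:
        e = {frozenset((t.compartment_a, t.compartment_b)) for t in self.tubes}
        if self.gate is not None:
            e.add(frozenset(("St", "T")))
        return e

    # -- serialisation ----------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping) -> "Topology":
        return cls(
            compartments=tuple(d["compartments"]),
            tubes=tuple(Tube(*t) for t in d.get("tubes", [])),
            floor_antennas=dict(d.get("floor_antennas", {})),
            gate=d.get("gate"),
            beams=dict(d.get("beams", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Topology":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Event log
# ---------------------------------------------------------------------------


@dataclass
class EventLog:
    """A validated, deterministically sorted detection-event table.

    Wraps a :class:`pandas.DataFrame` with columns ``timestamp`` (int ms),
    ``mouse_id``, ``sensor_id``, ``sensor_kind`` and ``extra`` (free-form
    annotation: gate direction, beam arm, empty string otherwise).
    ``malformed`` records rows that could not be parsed, as
    ``(line_number, reason)`` pairs — counted and reported, never silently
    dropped.
    """

    data: pd.DataFrame
    malformed: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise EventLogError(f"event log missing columns: {missing}")
        df = df[EVENT_COLUMNS].copy()
        df["timestamp"] = df["timestamp"].astype(np.int64)
        if len(df) and (df["timestamp"] < 0).any():
            raise EventLogError("negative timestamps in event log")
        bad_kind = set(df["sensor_kind"]) - set(SENSOR_KINDS)
        if bad_kind:
            raise EventLogError(f"unknown sensor kinds: {sorted(bad_kind)}")
        df = df.sort_values(
            ["timestamp", "sensor_id", "mouse_id"], kind="mergesort"
        ).reset_index(drop=True)
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def of_kind(self, *kinds: str) -> pd.DataFrame:
        return self.data[self.data["sensor_kind"].isin(kinds)]

    def validate_sensors(self, topology: Topology) -> None:
        """Raise :class:`EventLogError` naming any sensor id absent from the topology."""
        unknown = sorted(set(self.data["sensor_id"]) - topology.sensor_ids)
        if unknown:
            raise EventLogError(f"sensor ids absent from topology: {unknown}")


_DEFAULT_DIALECT: Mapping[str, int] = {
    "timestamp": 0,
    "mouse_id": 1,
    "sensor_id": 2,
    "sensor_kind": 3,
    "extra": 4,
}


def read_event_log(
    path: str | Path | io.TextIOBase,
    dialect: Mapping[str, int] | None = None,
    *,
    sep: str = "\t",
    header: bool = True,
    topology: Topology | None = None,
) -> EventLog:
    """Read a detection-event table from a delimited text file.

    Parameters
    ----------
    path
        File path or open text handle.
    dialect
        Mapping of field name (``timestamp``, ``mouse_id``, ``sensor_id``,
        ``sensor_kind`` and optionally ``extra``) to 0-based column index,
        for logs whose column order differs from the canonical one.
    sep, header
        Field separator and whether the first line is a header (skipped).
    topology
        If given, sensor ids are validated against it and an
        :class:`EventLogError` listing offenders is raised on mismatch.

    Returns
    -------
    EventLog
        Events sorted by the deterministic ``(timestamp, sensor_id,
        mouse_id)`` order.  Rows with the wrong field count are recorded in
        ``malformed``; an unparseable timestamp raises an error carrying
        the 1-based line number.
    """
    dialect = dict(_DEFAULT_DIALECT if dialect is None else dialect)
    required = {"timestamp", "mouse_id", "sensor_id", "sensor_kind"}
    if not required <= set(dialect):
        raise EventLogError(f"dialect must map {sorted(required)}")

    if isinstance(path, (str, Path)):
        fh: io.TextIOBase = open(path)  # noqa: SIM115 - closed below
        close = True
    else:
        fh, close = path, False
    rows: list[tuple] = []
    malformed: list[tuple[int, str]] = []
    try:
        n_fields = max(dialect.values()) + 1
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(sep)
            if len(parts) < n_fields:
                malformed.append((lineno, f"expected >= {n_fields} fields, got {len(parts)}"))
                continue
            raw_ts = parts[dialect["timestamp"]]
            try:
                ts = int(raw_ts)
            except ValueError:
                raise EventLogError(
                    f"line {lineno}: unparseable timestamp {raw_ts!r}"
                ) from None
            rows.append(
                (
                    ts,
                    parts[dialect["mouse_id"]],
                    parts[dialect["sensor_id"]],
                    parts[dialect["sensor_kind"]],
                    parts[dialect["extra"]] if "extra" in dialect and dialect["extra"] < len(parts) else "",
                )
            )
    finally:
        if close:
            fh.close()

    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    log = EventLog(df, malformed=malformed)
    if topology is not None:
        log.validate_sensors(topology)
    return log


def write_event_log(log: EventLog, path: str | Path) -> None:
    """Write an event log to the canonical TSV; round-trips bit-exactly."""
    log.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------


@dataclass
class SessionSchedule:
    """Ordered, non-overlapping experimental sessions.

    Each session is ``(label, t_start, t_end)`` with a half-open interval
    ``[t_start, t_end)`` in ms.  Typical labels: Ha (habituation), S1–S4.
    """

    sessions: Sequence[tuple[str, int, int]]

    def __post_init__(self) -> None:
        ss = [(str(l), int(a), int(b)) for l, a, b in self.sessions]
        for l, a, b in ss:
            if a >= b:
                raise ScheduleError(f"session {l!r} has non-positive duration")
        for (l1, _, e1), (l2, s2, _) in zip(ss, ss[1:]):
            if s2 < e1:
                raise ScheduleError(f"sessions {l1!r} and {l2!r} overlap")
        self.sessions = ss

    def label_for(self, t: int) -> str:
        for l, a, b in self.sessions:
            if a <= t < b:
                return l
        return "none"

    def boundaries(self) -> list[int]:
        out: list[int] = []
        for _, a, b in self.sessions:
            out.extend((a, b))
        return sorted(set(out))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionSchedule":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls([(s["label"], s["t_start"], s["t_end"]) for s in d["sessions"]])


def assign_sessions(
    records: pd.DataFrame, schedule: SessionSchedule, time_col: str = "timestamp"
) -> pd.DataFrame:
    """Annotate timestamped records with their session label.

    Each record is labelled by the unique session whose half-open interval
    contains its timestamp; records outside every session get ``"none"``.
    A timestamp exactly at one session's end and the next one's start
    belongs to the *next* session.
    """
    out = records.copy()
    t = out[time_col].to_numpy()
    labels = np.full(len(out), "none", dtype=object)
    for l, a, b in schedule.sessions:
        labels[(t >= a) & (t < b)] = l
    out["session"] = labels
    return out


def split_visits_by_session(
    visits: pd.DataFrame, schedule: SessionSchedule
) -> pd.DataFrame:
    """Split visits at session boundaries and label each piece.

    A visit spanning a boundary becomes two visits meeting at the boundary
    (half-open convention preserved).  Pieces outside all sessions are
    labelled ``"none"``.
    """
    cuts = schedule.boundaries()
    rows = []
    for rec in visits.itertuples(index=False):
        t0, t1 = int(rec.t_enter), int(rec.t_exit)
        pts = [t0] + [c for c in cuts if t0 < c < t1] + [t1]
        for a, b in zip(pts, pts[1:]):
            rows.append(
                {
                    "mouse_id": rec.mouse_id,
                    "compartment": rec.compartment,
                    "t_enter": a,
                    "t_exit": b,
                    "session": schedule.label_for(a),
                }
            )
    return pd.DataFrame(rows, columns=VISIT_COLUMNS + ["session"])


# ---------------------------------------------------------------------------
# Transition reconstruction
# ---------------------------------------------------------------------------


@dataclass
class AnomalyReport:
    """Counts of irregularities met while reconstructing movement.

    Nothing here is fatal: tube antennas are assumed reliable, so
    inconsistencies indicate log truncation or back-outs, and the
    reconstruction always trusts the most recent antenna evidence.

    Categories
    ----------
    same_antenna_repeat
        The mouse entered a tube and backed out (two consecutive
        detections on the same antenna); no transition is emitted.
    unpaired_detection
        A tube detection that was never matched by the opposite antenna
        of its tube (the next detection of that mouse was on a different
        tube, or the log ended).
    inconsistent_origin
        A reconstructed transition started from a compartment the mouse
        was not believed to be in; the location state was resynchronised
        to the antenna evidence.
    """

    counts: Counter = field(default_factory=Counter)
    details: list[dict] = field(default_factory=list)

    def add(self, category: str, **info) -> None:
        self.counts[category] += 1
        self.details.append({"category": category, **info})

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def reconstruct_transitions(
    events: EventLog, topology: Topology
) -> tuple[pd.DataFrame, AnomalyReport]:
    """Reconstruct directed compartment transitions from tube detections.

    For each mouse, tube-antenna detections are scanned in time order.  A
    pair of consecutive detections on the two antennas of the same tube
    yields one transition directed from the first antenna's compartment to
    the second's, with ``t_start``/``t_end`` the two detection times.  A
    repeated detection on the same antenna is a back-out and yields no
    transition.  Each mouse's location state machine is updated to the
    transition's destination; if a transition starts from a compartment
    the mouse is not currently in, the state is resynchronised (antenna
    evidence wins) and the event is logged.

    Returns
    -------
    (DataFrame, AnomalyReport)
        Transitions with columns ``mouse_id, from_compartment,
        to_compartment, t_start, t_end``, sorted by ``(t_start, t_end,
        mouse_id)``; and the anomaly report.
    """
    events.validate_sensors(topology)
    report = AnomalyReport()
    tube_events = events.of_kind("tube_antenna")
    rows: list[tuple] = []

    for mouse, grp in tube_events.groupby("mouse_id", sort=True):
        pending: tuple[int, str] | None = None  # (timestamp, antenna)
        location: str | None = None
        for ts, ant in zip(grp["timestamp"].to_numpy(), grp["sensor_id"].to_numpy()):
            ts = int(ts)
            if pending is None:
                pending = (ts, ant)
                continue
            p_ts, p_ant = pending
            if ant == p_ant:
                report.add("same_antenna_repeat", mouse_id=mouse, antenna=ant, t=ts)
                pending = None  # back-out: both detections consumed
                continue
            tube, side = topology.tube_for_antenna(p_ant)
            other = tube.antenna_b if side == "a" else tube.antenna_a
            if ant != other:
                # pending detection orphaned by a detection on another tube
                report.add("unpaired_detection", mouse_id=mouse, antenna=p_ant, t=p_ts)
                pending = (ts, ant)
                continue
            src = tube.compartment_a if side == "a" else tube.compartment_b
            dst = tube.compartment_b if side == "a" else tube.compartment_a
            if location is not None and location != src:
                report.add(
                    "inconsistent_origin",
                    mouse_id=mouse,
                    expected=location,
                    observed=src,
                    t=p_ts,
                )
            rows.append((mouse, src, dst, p_ts, ts))
            location = dst
            pending = None
        if pending is not None:
            report.add(
                "unpaired_detection", mouse_id=mouse, antenna=pending[1], t=pending[0]
            )

    df = pd.DataFrame(rows, columns=TRANSITION_COLUMNS)
    df = df.sort_values(["t_start", "t_end", "mouse_id"], kind="mergesort").reset_index(
        drop=True
    )
    return df, report


def build_visits(
    transitions: pd.DataFrame,
    *,
    include_tail: bool = False,
    log_end: int | None = None,
) -> pd.DataFrame:
    """Derive compartment visits from a transition table.

    Per mouse, visit *k* occupies the destination compartment of
    transition *k* over ``[t_end_k, t_end_{k+1})``.  The location before
    the first completed transition is unknown and produces no visit.  The
    open-ended tail after the last transition is excluded by default
    (unknown exit time); pass ``include_tail=True`` with ``log_end`` to
    close it at the end of the log.
    """
    if include_tail and log_end is None:
        raise ValueError("include_tail requires log_end")
    rows: list[tuple] = []
    for mouse, grp in transitions.groupby("mouse_id", sort=True):
        grp = grp.sort_values(["t_end", "t_start"], kind="mergesort")
        dests = grp["to_compartment"].to_numpy()
        ends = grp["t_end"].to_numpy()
        for k in range(len(grp) - 1):
            if ends[k + 1] > ends[k]:
                rows.append((mouse, dests[k], int(ends[k]), int(ends[k + 1])))
        if include_tail and len(grp) and log_end > ends[-1]:
            rows.append((mouse, dests[-1], int(ends[-1]), int(log_end)))
    df = pd.DataFrame(rows, columns=VISIT_COLUMNS)
    return df.sort_values(["mouse_id", "t_enter"], kind="mergesort").reset_index(drop=True)
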