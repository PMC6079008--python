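"""Social metrics from co-housed detection streams.

Who is with whom (co-presence), who moves first (lead/follow and the
peri-event time histogram of paired transitions), and who chases whom
(concomitant detections along consecutive antennas).

Floor-antenna-derived measures such as chasing are quarantined: floor
detection misses ~25% of crossings, so by default chasing statistics are
kept out of profile building and must be requested explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .activity import _gaussian_kde

__all__ = [
    "copresence",
    "lead_follow",
    "transition_peth",
    "ChasingEpisode",
    "chasing_episodes",
]

MS = 1000  # ms per second


def copresence(visits: pd.DataFrame) -> pd.DataFrame:
    """Classify every instant of each mouse's tracked time by company.

    A sweep-line over the visit intervals of each compartment counts, for
    every elementary interval, how many mice are present; each present
    mouse accumulates that interval's duration into one of four buckets:
    alone, with exactly one, exactly two, or three-or-more others.

    Returns
    -------
    pandas.DataFrame
        One row per mouse with columns ``alone_ms, with_one_ms,
        with_two_ms, with_three_plus_ms, tracked_ms``; the four buckets
        partition the tracked time exactly.
    """
    mice = sorted(visits["mouse_id"].unique())
    buckets = {m: np.zeros(4, dtype=np.int64) for m in mice}
    for _, comp_visits in visits.groupby("compartment"):
        marks: list[tuple[int, int, str]] = []
        for rec in comp_visits.itertuples(index=False):
            marks.append((int(rec.t_enter), 1, rec.mouse_id))
            marks.append((int(rec.t_exit), 0, rec.mouse_id))
        # process exits before entries at equal time (half-open intervals)
        marks.sort(key=lambda m: (m[0], m[1], m[2]))
        present: set[str] = set()
        prev_t: int | None = None
        for t, kind, mouse in marks:
            if present and prev_t is not None and t > prev_t:
                k = min(len(present) - 1, 3)
                for m in present:
                    buckets[m][k] += t - prev_t
            if kind == 1:
                present.add(mouse)
            else:
                present.discard(mouse)
            prev_t = t
    rows = [
        {
            "mouse_id": m,
            "alone_ms": int(b[0]),
            "with_one_ms": int(b[1]),
            "with_two_ms": int(b[2]),
            "with_three_plus_ms": int(b[3]),
            "tracked_ms": int(b.sum()),
        }
        for m, b in buckets.items()
    ]
    return pd.DataFrame(rows)


def lead_follow(
    transitions: pd.DataFrame,
    *,
    window_s: float = 5.0,
    duration_ms: int | None = None,
) -> pd.DataFrame:
    """Count leads and follows over paired same-destination transitions.

    Whenever two distinct mice arrive in the same compartment with an
    arrival-time lag in ``(0, window_s]`` seconds, the earlier mouse
    scores a lead and the later a follow.  Each follower arrival is
    paired with its nearest preceding leader arrival, and a leader
    arrival is credited at most once per other mouse, so the global
    pairing conserves ``sum(leads) == sum(follows)``.  Simultaneous
    arrivals (lag exactly 0) are discarded: no order is determinable.

    The lead ratio ``LF = leads / (leads + follows)`` is NaN when a mouse
    has no paired transition at all (undefined, not 0).  If
    ``duration_ms`` is given, per-hour rates are added.
    """
    window_ms = int(round(window_s * MS))
    mice = sorted(transitions["mouse_id"].unique())
    leads = {m: 0 for m in mice}
    follows = {m: 0 for m in mice}
    for _, grp in transitions.groupby("to_compartment"):
        by_mouse = {
            m: np.sort(g["t_end"].to_numpy())
            for m, g in grp.groupby("mouse_id")
        }
        for fol in by_mouse:
            for led in by_mouse:
                if led == fol:
                    continue
                lead_times = by_mouse[led]
                used = -1  # index of last consumed lead arrival
                for t in by_mouse[fol]:
                    # nearest preceding arrival of `led` within the window
                    i = int(np.searchsorted(lead_times, t, side="left")) - 1
                    if i > used and t - lead_times[i] <= window_ms and t > lead_times[i]:
                        leads[led] += 1
                        follows[fol] += 1
                        used = i
    rows = []
    for m in mice:
        tot = leads[m] + follows[m]
        row = {
            "mouse_id": m,
            "n_leads": leads[m],
            "n_follows": follows[m],
            "lf": leads[m] / tot if tot else float("nan"),
        }
        if duration_ms is not None:
            hours = duration_ms / 3_600_000
            row["leads_per_hour"] = leads[m] / hours
            row["follows_per_hour"] = follows[m] / hours
        rows.append(row)
    return pd.DataFrame(rows)


def transition_peth(
    transitions: pd.DataFrame,
    *,
    window_s: float = 10.0,
    bandwidth_s: float = 2.0,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Peri-event time histogram of paired same-destination transitions.

    For every arrival of a mouse into a compartment, the arrival lags of
    *other* mice into the same compartment within ``±window_s`` are
    collected; a Gaussian kernel density (fixed bandwidth, default 2 s)
    over the pooled lags is returned.  Social attraction shows up as a
    peak near lag 0; independent movers give a flat profile.

    Returns the raw lags (seconds; positive = other mouse arrived later)
    and a tidy frame with columns ``lag_s, density``.
    """
    window_ms = int(round(window_s * MS))
    lags: list[float] = []
    for _, grp in transitions.groupby("to_compartment"):
        t = grp["t_end"].to_numpy()
        mouse = grp["mouse_id"].to_numpy()
        order = np.argsort(t, kind="stable")
        t, mouse = t[order], mouse[order]
        for i in range(len(t)):
            lo = np.searchsorted(t, t[i] - window_ms, side="left")
            hi = np.searchsorted(t, t[i] + window_ms, side="right")
            for j in range(lo, hi):
                if j != i and mouse[j] != mouse[i]:
                    lags.append((t[j] - t[i]) / MS)
    lags_arr = np.asarray(lags, dtype=float)
    if grid is None:
        grid = np.linspace(-window_s, window_s, 201)
    if len(lags_arr) == 0:
        dens = np.zeros_like(grid)
    else:
        dens = _gaussian_kde(grid, lags_arr, bandwidth_s)
    return lags_arr, pd.DataFrame({"lag_s": grid, "density": dens})


@dataclass
class ChasingEpisode:
    """One chase: two mice detected concomitantly on >= 2 consecutive antennas.

    The leader is the first-detected mouse on the first antenna and
    precedes the follower on every antenna of the episode; within-antenna
    lags are at most the concomitance window, between-antenna (leader)
    lags at most the consecutiveness window.
    """

    leader_id: str
    follower_id: str
    antennas: list[str] = field(default_factory=list)
    times: list[tuple[int, int]] = field(default_factory=list)  # (t_leader, t_follower) ms

    @property
    def n_antennas(self) -> int:
        return len(self.antennas)


def chasing_episodes(
    events: pd.DataFrame,
    *,
    concomitant_s: float = 5.0,
    consecutive_s: float = 30.0,
    sensor_kinds: Sequence[str] = ("tube_antenna", "floor_antenna"),
) -> tuple[list[ChasingEpisode], pd.DataFrame]:
    """Detect chasing episodes from tube and floor detections.

    Two mice are *concomitant* on an antenna when they are detected there
    within ``concomitant_s`` of each other (consecutive detections in the
    antenna's stream); two antennas are *consecutive* when the leading
    mouse reappears on a different antenna within ``consecutive_s``.  A
    chasing episode is a maximal chain of concomitant detections of the
    same ordered pair across at least two consecutive antennas.

    Returns the episodes and a per-mouse chase lead/follow table
    (``mouse_id, n_chase_leads, n_chase_follows, chase_lf``).
    """
    df = events[events["sensor_kind"].isin(sensor_kinds)]
    conc_ms = int(round(concomitant_s * MS))
    consec_ms = int(round(consecutive_s * MS))

    # concomitant records: (t_leader, antenna, leader, follower, t_follower)
    records: list[tuple[int, str, str, str, int]] = []
    for ant, grp in df.groupby("sensor_id"):
        t = grp["timestamp"].to_numpy()
        mouse = grp["mouse_id"].to_numpy()
        order = np.lexsort((mouse, t))
        t, mouse = t[order], mouse[order]
        for i in range(len(t) - 1):
            if mouse[i] != mouse[i + 1] and t[i + 1] - t[i] <= conc_ms:
                records.append((int(t[i]), ant, mouse[i], mouse[i + 1], int(t[i + 1])))
    records.sort()

    episodes: list[ChasingEpisode] = []
    open_chains: dict[tuple[str, str], ChasingEpisode] = {}

    def _close(key: tuple[str, str]) -> None:
        ep = open_chains.pop(key, None)
        if ep is not None and ep.n_antennas >= 2:
            episodes.append(ep)

    for t_lead, ant, leader, follower, t_fol in records:
        key = (leader, follower)
        ep = open_chains.get(key)
        if ep is not None:
            last_ant = ep.antennas[-1]
            last_t = ep.times[-1][0]
            if ant != last_ant and t_lead - last_t <= consec_ms:
                ep.antennas.append(ant)
                ep.times.append((t_lead, t_fol))
                continue
            _close(key)
        open_chains[key] = ChasingEpisode(leader, follower, [ant], [(t_lead, t_fol)])
    for key in list(open_chains):
        _close(key)

    mice = sorted(df["mouse_id"].unique())
    n_lead = {m: 0 for m in mice}
    n_fol = {m: 0 for m in mice}
    for ep in episodes:
        n_lead[ep.leader_id] += 1
        n_fol[ep.follower_id] += 1
    rows = []
    for m in mice:
        tot = n_lead[m] + n_fol[m]
        rows.append(
            {
                "mouse_id": m,
                "n_chase_leads": n_lead[m],
                "n_chase_follows": n_fol[m],
                "chase_lf": n_lead[m] / tot if tot else float("nan"),
            }
        )
    return episodes, pd.DataFrame(rows)
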