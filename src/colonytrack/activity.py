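"""Per-mouse general-activity measures.

Occupancy proportions and their entropy, circadian event histograms,
visit-duration densities on a log scale, daily event counts and
cumulative dark-phase curves — the descriptive layer on top of the
reconstructed visits and the raw detection stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OccupancyProfile",
    "occupancy_profile",
    "occupancy_entropy",
    "circadian_histogram",
    "visit_duration_density",
    "events_per_day",
    "cumulative_dark_phase",
    "dark_phase_mask",
]

MS_PER_DAY = 86_400_000
MS_PER_MIN = 60_000


@dataclass
class OccupancyProfile:
    """Proportion of tracked time a mouse spent in each compartment.

    Proportions are non-negative and sum to one over the tracked time
    (the union of the mouse's visits within the selection).
    """

    mouse_id: str
    session: str
    proportions: Mapping[str, float]

    def as_array(self, order: Sequence[str] | None = None) -> np.ndarray:
        keys = list(self.proportions) if order is None else list(order)
        return np.array([self.proportions.get(k, 0.0) for k in keys])


def occupancy_profile(
    visits: pd.DataFrame,
    mouse_id: str,
    session: str | None = None,
    compartments: Sequence[str] | None = None,
) -> OccupancyProfile:
    """Compute the occupancy proportions of one mouse.

    Parameters
    ----------
    visits
        Visit table (``mouse_id, compartment, t_enter, t_exit`` and
        optionally ``session``).
    mouse_id
        Which mouse.
    session
        If given, restrict to visits carrying this session label (the
        table must then have a ``session`` column).
    compartments
        Compartments to report; those without visits get proportion 0.
        Defaults to the compartments present in the selection.

    Raises
    ------
    ValueError
        If the mouse has zero tracked time in the selection.
    """
    sel = visits[visits["mouse_id"] == mouse_id]
    if session is not None:
        sel = sel[sel["session"] == session]
    durations = (sel["t_exit"] - sel["t_enter"]).to_numpy(dtype=float)
    total = durations.sum()
    if total <= 0:
        raise ValueError(f"no occupancy data for mouse {mouse_id!r}"
                         + (f" in session {session!r}" if session else ""))
    per_comp = sel.assign(dur=durations).groupby("compartment")["dur"].sum() / total
    props = {c: 0.0 for c in (compartments or [])}
    props.update(per_comp.to_dict())
    return OccupancyProfile(mouse_id, session or "all", props)


def occupancy_entropy(profile: OccupancyProfile | Mapping[str, float]) -> float:
    """Shannon entropy of an occupancy profile, in nats.

    ``H = -sum_i p_i ln p_i`` with the convention ``0 ln 0 = 0``.  Low
    entropy marks a territorial animal confined to one compartment; the
    maximum ``ln K`` is reached for uniform use of all K compartments.
    """
    props = profile.proportions if isinstance(profile, OccupancyProfile) else profile
    p = np.asarray(list(props.values()), dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def circadian_histogram(
    timestamps_ms: Sequence[int] | np.ndarray,
    *,
    bin_minutes: int = 10,
    epoch_offset_min: int = 0,
    per_day: bool = True,
    n_days: float | None = None,
) -> pd.Series:
    """Fold detection events onto a 24 h dial and bin them.

    Parameters
    ----------
    timestamps_ms
        Event times in ms since the experiment epoch.
    bin_minutes
        Bin width; must divide 1440 (default 10 min -> 144 bins).
    epoch_offset_min
        Clock time of the experiment epoch, in minutes after midnight
        (e.g. 19 h -> 1140), so bins align with the wall clock.
    per_day
        Normalise counts by the number of days covered.
    n_days
        Override the day count used for normalisation; defaults to the
        observed span rounded up to a full day.

    Returns
    -------
    pandas.Series
        Indexed by bin start in minutes after midnight; counts (or counts
        per day).  The raw histogram totals the number of events.
    """
    if 1440 % bin_minutes != 0:
        raise ValueError(f"bin_minutes={bin_minutes} does not divide 1440")
    t = np.asarray(timestamps_ms, dtype=np.int64)
    n_bins = 1440 // bin_minutes
    minute_of_day = (t // MS_PER_MIN + epoch_offset_min) % 1440
    counts, _ = np.histogram(minute_of_day, bins=n_bins, range=(0, 1440))
    counts = counts.astype(float)
    if per_day:
        if n_days is None:
            n_days = max(1.0, float(np.ceil((t.max() - t.min() + 1) / MS_PER_DAY))) if len(t) else 1.0
        counts /= n_days
    idx = np.arange(n_bins) * bin_minutes
    return pd.Series(counts, index=idx, name="events")


def _gaussian_kde(x: np.ndarray, samples: np.ndarray, bandwidth: float) -> np.ndarray:
    # fixed absolute bandwidth; tolerant of zero-variance samples
    z = (x[:, None] - samples[None, :]) / bandwidth
    return np.exp(-0.5 * z**2).sum(axis=1) / (len(samples) * bandwidth * np.sqrt(2 * np.pi))


def visit_duration_density(
    visits: pd.DataFrame,
    *,
    bandwidth: float = 0.1,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Kernel density of visit durations on a log10-minute scale.

    A Gaussian kernel with a fixed bandwidth (default 0.1 log10 units)
    is applied per compartment to ``log10(duration in minutes)``; this is
    how long home-cage stays (hours in the nest) and quick passages
    (seconds in a corridor) become separable modes.

    Returns a tidy frame with columns ``compartment, log10_minutes,
    density``; each compartment's density integrates to one.
    """
    if len(visits) == 0:
        raise ValueError("no visits to estimate a density from")
    dur_min = (visits["t_exit"] - visits["t_enter"]).to_numpy(dtype=float) / MS_PER_MIN
    if (dur_min <= 0).any():
        raise ValueError("non-positive visit durations")
    logd = np.log10(dur_min)
    if grid is None:
        lo, hi = logd.min() - 4 * bandwidth, logd.max() + 4 * bandwidth
        grid = np.linspace(lo - 0.5, hi + 0.5, 512)
    out = []
    for comp, idx in visits.groupby("compartment").indices.items():
        dens = _gaussian_kde(grid, logd[idx], bandwidth)
        out.append(pd.DataFrame(
            {"compartment": comp, "log10_minutes": grid, "density": dens}
        ))
    return pd.concat(out, ignore_index=True)


def events_per_day(events: pd.DataFrame, *, duration_ms: int | None = None) -> pd.Series:
    """Tube-antenna detections per day, per mouse.

    ``events`` is an event table (or the ``data`` of an ``EventLog``);
    only rows of kind ``tube_antenna`` are counted.  ``duration_ms``
    defaults to the observed span of the whole table.
    """
    tube = events[events["sensor_kind"] == "tube_antenna"]
    if duration_ms is None:
        t = events["timestamp"]
        duration_ms = int(t.max() - t.min()) if len(t) else 0
    if duration_ms <= 0:
        raise ValueError("cannot normalise by a non-positive duration")
    days = duration_ms / MS_PER_DAY
    return tube.groupby("mouse_id").size() / days


def dark_phase_mask(
    timestamps_ms: np.ndarray,
    *,
    epoch_offset_min: int = 0,
    lights_on_min: int = 420,
    lights_off_min: int = 1140,
) -> np.ndarray:
    """Boolean mask of events falling in the dark phase.

    Default schedule: lights on at 07:00, off at 19:00, so the dark phase
    runs 19:00-07:00 and wraps around midnight.
    """
    t = np.asarray(timestamps_ms, dtype=np.int64)
    minute_of_day = (t // MS_PER_MIN + epoch_offset_min) % 1440
    if lights_off_min > lights_on_min:
        return (minute_of_day >= lights_off_min) | (minute_of_day < lights_on_min)
    return (minute_of_day >= lights_off_min) & (minute_of_day < lights_on_min)


def cumulative_dark_phase(
    timestamps_ms: np.ndarray,
    values: np.ndarray | None = None,
    *,
    epoch_offset_min: int = 0,
    lights_on_min: int = 420,
    lights_off_min: int = 1140,
) -> pd.Series:
    """Cumulative per-night dark-phase totals.

    Each event (or value at an event time) is assigned to the night it
    falls in — a night spans lights-off to the following lights-on — and
    night totals are summed cumulatively across nights, reproducing the
    divergence-over-time view of individual activity curves.  Events in
    the light phase contribute nothing.

    Returns a series indexed by night number (0-based, in order of
    occurrence) holding the running totals.
    """
    t = np.asarray(timestamps_ms, dtype=np.int64)
    v = np.ones(len(t)) if values is None else np.asarray(values, dtype=float)
    if len(t) == 0:
        return pd.Series(dtype=float)
    mask = dark_phase_mask(
        t, epoch_offset_min=epoch_offset_min,
        lights_on_min=lights_on_min, lights_off_min=lights_off_min,
    )
    abs_min = t // MS_PER_MIN + epoch_offset_min
    # night index: which lights-off boundary most recently passed
    night = (abs_min - lights_off_min) // 1440
    n0, n1 = int(night.min()), int(night.max())
    totals = np.zeros(n1 - n0 + 1)
    np.add.at(totals, (night - n0)[mask], v[mask])
    return pd.Series(np.cumsum(totals), index=np.arange(n0, n1 + 1) - n0, name="cumulative")
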