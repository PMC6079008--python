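"""Seeded generators for every input the pipeline consumes.

No public dataset of this kind of group-housed RFID experiment is
available, so the package ships first-class simulators with known ground
truth, emulating the statistical structure the analyses assume:

* a colony of mice moving over the compartment graph as independent
  continuous-time Markov chains with circadian rate modulation and
  optional leader-follower coupling, observed through tube antennas
  (fully reliable by default) and floor antennas (75% reliable, no false
  positives);
* softmax reinforcement-learning (or side-biased / random) choice agents
  run against a bottle-swap schedule;
* bursty dopamine spike trains built so that every planted burst
  satisfies, and every tonic gap violates, the 80/160 ms detection
  criteria — ground-truth %SWB is exact by construction.

Every generator is driven by a single integer seed and is bit-identical
across runs with the same seed.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .choice import REWARD, SwapSchedule, softmax_prob, update_values
from .events import EventLog, Topology, Tube, TRANSITION_COLUMNS, VISIT_COLUMNS
from .spikes import SpikeTrain

__all__ = [
    "default_topology",
    "ColonyConfig",
    "SimulatedColony",
    "simulate_colony",
    "stationary_occupancy",
    "ChoiceAgentConfig",
    "SimulatedChoices",
    "simulate_choices",
    "SWITCHER_PHENOTYPES",
    "simulate_switcher_cohort",
    "SpikeSimConfig",
    "SimulatedSpikeTrain",
    "simulate_spike_train",
]

MS_PER_HOUR = 3_600_000
MS_PER_MIN = 60_000


def default_topology() -> Topology:
    """The canonical environment: NC, FC, CC, St social cage + gated T-maze.

    Nest (NC) and food (FC) compartments connect to a central compartment
    (CC) by antenna-paired tubes; CC connects to the stairs (St), from
    which a gate controls access to the T-maze (T) with one infrared beam
    per arm.  Floor antennas cover the four social-cage compartments.
    """
    return Topology(
        compartments=("NC", "FC", "CC", "St", "T"),
        tubes=(
            Tube("a_NC", "a_CC1", "NC", "CC"),
            Tube("a_FC", "a_CC2", "FC", "CC"),
            Tube("a_CC3", "a_St", "CC", "St"),
        ),
        floor_antennas={"f_NC": "NC", "f_FC": "FC", "f_CC": "CC", "f_St": "St"},
        gate="gate",
        beams={"beam_L": "L", "beam_R": "R"},
    )


# ---------------------------------------------------------------------------
# Colony simulator
# ---------------------------------------------------------------------------


@dataclass
class ColonyConfig:
    """Parameters of the colony movement simulator.

    Movement is a continuous-time Markov chain per mouse over the
    tube-connected compartments, with all rates multiplied by
    ``dark_multiplier`` during the dark phase (mice are nocturnal) and by
    a per-mouse lognormal factor for heterogeneity.  Follower mice copy
    their leader's transition with probability ``prob`` after a short
    lag, provided they are in the leader's source compartment.
    """

    topology: Topology = field(default_factory=default_topology)
    n_mice: int = 10
    #: symmetric per-edge transition rate, per hour, used when
    #: ``rate_matrix`` is not given
    base_rate_per_h: float = 15.0
    #: optional directed rates {(src, dst): per hour}
    rate_matrix: Mapping[tuple[str, str], float] | None = None
    #: sigma of the lognormal per-mouse rate multiplier (0 = homogeneous)
    rate_multiplier_sigma: float = 0.0
    dark_multiplier: float = 2.0
    #: clock time of t=0 in minutes after midnight (default 19:00)
    epoch_offset_min: int = 1140
    lights_on_min: int = 420
    lights_off_min: int = 1140
    #: follower -> (leader, follow probability)
    followers: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    follow_lag_s: tuple[float, float] = (1.0, 3.0)
    tube_p: float = 1.0
    floor_p: float = 0.75
    transit_ms: tuple[int, int] = (300, 1500)
    duration_ms: int = 24 * MS_PER_HOUR
    seed: int = 0

    def mouse_ids(self) -> list[str]:
        return [f"m{i + 1:02d}" for i in range(self.n_mice)]


@dataclass
class SimulatedColony:
    """Colony simulation output: the observed event log plus ground truth."""

    events: EventLog
    true_transitions: pd.DataFrame
    true_visits: pd.DataFrame
    #: planted lead/follow counts per mouse (from executed follow events)
    true_lead_follow: pd.DataFrame
    #: arrivals into floor-covered compartments and how many were detected
    n_floor_crossings: int
    n_floor_detected: int
    config: ColonyConfig


def _directed_rates(cfg: ColonyConfig) -> dict[str, list[tuple[str, float, Tube, str]]]:
    """Out-rates per compartment: (destination, rate/h, tube, direction)."""
    out: dict[str, list[tuple[str, float, Tube, str]]] = {}
    for tube in cfg.topology.tubes:
        for src, dst, direction in (
            (tube.compartment_a, tube.compartment_b, "ab"),
            (tube.compartment_b, tube.compartment_a, "ba"),
        ):
            rate = cfg.base_rate_per_h
            if cfg.rate_matrix is not None:
                rate = float(cfg.rate_matrix.get((src, dst), 0.0))
            if rate > 0:
                out.setdefault(src, []).append((dst, rate, tube, direction))
    return out


def stationary_occupancy(cfg: ColonyConfig) -> dict[str, float]:
    """Stationary distribution of the movement chain over compartments.

    Solves the global balance equations of the (un-modulated) rate
    matrix.  Uniform circadian scaling and per-mouse rate multipliers
    leave this distribution unchanged, so it is the long-run occupancy
    prediction for every mouse.
    """
    out = _directed_rates(cfg)
    comps = sorted(set(out) | {d for lst in out.values() for d, *_ in lst})
    idx = {c: i for i, c in enumerate(comps)}
    Q = np.zeros((len(comps), len(comps)))
    for src, lst in out.items():
        for dst, rate, *_ in lst:
            Q[idx[src], idx[dst]] += rate
            Q[idx[src], idx[src]] -= rate
    A = np.vstack([Q.T, np.ones(len(comps))])
    b = np.zeros(len(comps) + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return {c: float(pi[idx[c]]) for c in comps}


def simulate_colony(config: ColonyConfig) -> SimulatedColony:
    """Simulate colony movement and its detection by the antenna system.

    Each true tube crossing emits the source-side antenna detection at
    the crossing start and the destination-side detection at its end;
    the pair is observed with probability ``tube_p`` (misses drop both
    detections — a truncated log, not sensor noise).  Each arrival into a
    floor-covered compartment is a floor-crossing opportunity detected
    with probability ``floor_p``; there are no false positives.

    Returns the event log together with the true transition list, true
    visits, and the planted lead/follow counts, enabling exact
    end-to-end recovery tests downstream.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    out_rates = _directed_rates(cfg)
    if not out_rates:
        raise ValueError("topology has no tube-connected compartments")
    move_comps = sorted(out_rates)
    mice = cfg.mouse_ids()
    for f, (leader, _) in cfg.followers.items():
        if f not in mice or leader not in mice:
            raise ValueError(f"unknown follower/leader pair {f!r} -> {leader!r}")

    mult = (
        np.exp(rng.normal(0.0, cfg.rate_multiplier_sigma, size=len(mice)))
        if cfg.rate_multiplier_sigma > 0
        else np.ones(len(mice))
    )
    m_mult = dict(zip(mice, mult))

    loc = {m: move_comps[rng.integers(len(move_comps))] for m in mice}
    version = {m: 0 for m in mice}
    busy_until = {m: 0 for m in mice}
    last_tube_ms = {m: -1 for m in mice}

    dark_hi = max(1.0, cfg.dark_multiplier)

    def is_dark(t_ms: float) -> bool:
        mod = (int(t_ms) // MS_PER_MIN + cfg.epoch_offset_min) % 1440
        if cfg.lights_off_min > cfg.lights_on_min:
            return mod >= cfg.lights_off_min or mod < cfg.lights_on_min
        return cfg.lights_off_min <= mod < cfg.lights_on_min

    def sample_wait_ms(mouse: str, t0: float) -> float:
        """Thinning sampler for the next departure under circadian rates."""
        base = sum(r for _, r, *_ in out_rates[loc[mouse]]) * m_mult[mouse]
        r_max = base * dark_hi
        t = t0
        while True:
            t += rng.exponential(1.0 / r_max) * MS_PER_HOUR
            r_now = base * (cfg.dark_multiplier if is_dark(t) else 1.0)
            if rng.random() < r_now / r_max:
                return t - t0

    heap: list[tuple[int, int, int, str, tuple]] = []
    seq = 0

    def push(t_ms: int, kind: int, mouse: str, payload: tuple) -> None:
        nonlocal seq
        heapq.heappush(heap, (int(t_ms), seq, kind, mouse, payload))
        seq += 1

    for m in mice:
        push(int(sample_wait_ms(m, 0.0)), 0, m, ("depart", version[m]))

    ev_rows: list[tuple] = []  # (timestamp, mouse, sensor, kind, extra)
    tr_rows: list[tuple] = []
    arrivals: dict[str, list[tuple[str, int]]] = {m: [] for m in mice}
    planted_leads = {m: 0 for m in mice}
    planted_follows = {m: 0 for m in mice}
    n_floor, n_floor_det = 0, 0

    def execute_crossing(mouse: str, t_ms: int, forced: tuple | None) -> tuple[str, int] | None:
        """Run one tube crossing starting at ``t_ms``; returns (src, t_end)."""
        nonlocal n_floor, n_floor_det
        src = loc[mouse]
        if forced is not None:
            dst, tube, direction = forced
        else:
            options = out_rates[src]
            rates = np.array([r for _, r, *_ in options])
            dst, _, tube, direction = options[rng.choice(len(options), p=rates / rates.sum())]
        t_start = max(int(t_ms), last_tube_ms[mouse] + 1)
        t_end = t_start + int(rng.integers(cfg.transit_ms[0], cfg.transit_ms[1] + 1))
        tr_rows.append((mouse, src, dst, t_start, t_end))
        if rng.random() < cfg.tube_p:
            first, second = (
                (tube.antenna_a, tube.antenna_b) if direction == "ab"
                else (tube.antenna_b, tube.antenna_a)
            )
            ev_rows.append((t_start, mouse, first, "tube_antenna", ""))
            ev_rows.append((t_end, mouse, second, "tube_antenna", ""))
        last_tube_ms[mouse] = t_end
        floor_ant = next(
            (a for a, c in cfg.topology.floor_antennas.items() if c == dst), None
        )
        if floor_ant is not None:
            n_floor += 1
            if rng.random() < cfg.floor_p:
                n_floor_det += 1
                ev_rows.append(
                    (t_end + int(rng.integers(100, 500)), mouse, floor_ant,
                     "floor_antenna", "")
                )
        loc[mouse] = dst
        busy_until[mouse] = t_end
        arrivals[mouse].append((dst, t_end))
        return src, t_end

    while heap:
        t_ms, _, kind, mouse, payload = heapq.heappop(heap)
        if t_ms >= cfg.duration_ms:
            continue
        if payload[0] == "depart":
            if payload[1] != version[mouse]:
                continue  # superseded by a forced follow
            src, t_end = execute_crossing(mouse, t_ms, None)
            dst = loc[mouse]
            version[mouse] += 1
            push(t_end + int(sample_wait_ms(mouse, t_end)), 0, mouse,
                 ("depart", version[mouse]))
            # trigger followers of this mouse
            for fol, (leader, prob) in cfg.followers.items():
                if leader == mouse and loc[fol] == src and busy_until[fol] <= t_end:
                    if rng.random() < prob:
                        lag = rng.uniform(*cfg.follow_lag_s) * 1000.0
                        tube, direction = _tube_between(cfg.topology, src, dst)
                        push(int(t_end + lag), 1, fol,
                             ("follow", mouse, src, dst, tube, direction))
        else:  # follow
            _, leader, src, dst, tube, direction = payload
            if loc[mouse] != src or busy_until[mouse] > t_ms:
                continue  # follower moved on its own in the meantime
            _, t_end = execute_crossing(mouse, t_ms, (dst, tube, direction))
            planted_leads[leader] += 1
            planted_follows[mouse] += 1
            version[mouse] += 1
            push(t_end + int(sample_wait_ms(mouse, t_end)), 0, mouse,
                 ("depart", version[mouse]))

    events = EventLog(pd.DataFrame(
        ev_rows, columns=["timestamp", "mouse_id", "sensor_id", "sensor_kind", "extra"]
    ))
    transitions = (
        pd.DataFrame(tr_rows, columns=TRANSITION_COLUMNS)
        .sort_values(["t_start", "t_end", "mouse_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    vis_rows = []
    for m in mice:
        arr = arrivals[m]
        for (c0, t0), (_, t1) in zip(arr, arr[1:]):
            vis_rows.append((m, c0, t0, t1))
    visits = (
        pd.DataFrame(vis_rows, columns=VISIT_COLUMNS)
        .sort_values(["mouse_id", "t_enter"], kind="mergesort")
        .reset_index(drop=True)
    )
    lf = pd.DataFrame(
        {
            "mouse_id": mice,
            "planted_leads": [planted_leads[m] for m in mice],
            "planted_follows": [planted_follows[m] for m in mice],
        }
    )
    return SimulatedColony(events, transitions, visits, lf, n_floor, n_floor_det, cfg)


def _tube_between(topology: Topology, src: str, dst: str) -> tuple[Tube, str]:
    for tube in topology.tubes:
        if (tube.compartment_a, tube.compartment_b) == (src, dst):
            return tube, "ab"
        if (tube.compartment_b, tube.compartment_a) == (src, dst):
            return tube, "ba"
    raise ValueError(f"no tube between {src!r} and {dst!r}")


# ---------------------------------------------------------------------------
# Choice agents
# ---------------------------------------------------------------------------


@dataclass
class ChoiceAgentConfig:
    """Parameters of a simulated T-maze choice agent.

    Kinds: ``rl`` — a softmax reinforcement learner with learning rate
    ``alpha``, inverse temperature ``beta`` and the given update rule;
    ``side_biased`` — chooses left with fixed probability ``p_left``
    (p_left near 1 emulates a low-switcher that ignores the reward
    location); ``random`` — unbiased coin flips.
    """

    kind: str = "rl"
    alpha: float = 0.3
    beta: float = 2.0
    rule: str = "delta"
    p_left: float = 0.5
    n_trials: int = 300
    #: bottles swapped every this many trials (None = never)
    swap_every: int | None = 50
    initial_contents: tuple[str, str] = ("water", "sucrose")
    mean_gap_s: float = 120.0
    mouse_id: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("rl", "side_biased", "random"):
            raise ValueError(f"unknown agent kind {self.kind!r}")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if not (0.0 <= self.p_left <= 1.0):
            raise ValueError("p_left must be in [0, 1]")
        for c in self.initial_contents:
            if c not in REWARD:
                raise ValueError(f"unknown bottle content {c!r}")


@dataclass
class SimulatedChoices:
    """Simulated trial table plus the schedule and generating truth."""

    trials: pd.DataFrame
    schedule: SwapSchedule
    config: ChoiceAgentConfig


def simulate_choices(config: ChoiceAgentConfig) -> SimulatedChoices:
    """Generate a choice sequence under a bottle-swap schedule.

    Trial timing: inter-trial gaps are exponential with mean
    ``mean_gap_s``; entry-to-choice and choice-to-exit latencies are a
    few seconds.  Swaps exchange the two bottle contents every
    ``swap_every`` trials, timed at the entry of the first trial of the
    new block (so outcomes respect the half-open swap convention).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # trial skeleton: entry/choice/exit times in ms
    t = 0.0
    t_entry = np.empty(cfg.n_trials)
    t_choice = np.empty(cfg.n_trials)
    t_exit = np.empty(cfg.n_trials)
    for k in range(cfg.n_trials):
        t_entry[k] = t
        t_choice[k] = t + rng.uniform(5.0, 15.0) * 1000.0
        t_exit[k] = t_choice[k] + rng.uniform(10.0, 30.0) * 1000.0
        t = t_exit[k] + rng.exponential(cfg.mean_gap_s) * 1000.0

    entries = [(0, *cfg.initial_contents)]
    if cfg.swap_every:
        left, right = cfg.initial_contents
        for j in range(cfg.swap_every, cfg.n_trials, cfg.swap_every):
            left, right = right, left
            entries.append((int(t_entry[j]), left, right))
    schedule = SwapSchedule(entries)

    v = np.zeros(2)
    sides: list[str] = []
    outcomes: list[str] = []
    for k in range(cfg.n_trials):
        if cfg.kind == "rl":
            p_left = softmax_prob(v, cfg.beta)[0]
        elif cfg.kind == "side_biased":
            p_left = cfg.p_left
        else:
            p_left = 0.5
        side = "L" if rng.random() < p_left else "R"
        outcome = schedule.outcome(side, int(t_choice[k]))
        if cfg.kind == "rl":
            v = update_values(v, 0 if side == "L" else 1, REWARD[outcome],
                              cfg.alpha, rule=cfg.rule)
        sides.append(side)
        outcomes.append(outcome)

    trials = pd.DataFrame(
        {
            "mouse_id": cfg.mouse_id,
            "t_entry": t_entry.astype(np.int64),
            "t_choice": t_choice.astype(np.int64),
            "t_exit": t_exit.astype(np.int64),
            "side": sides,
            "outcome": outcomes,
        }
    )
    return SimulatedChoices(trials, schedule, cfg)


#: group-typical (centre, sd) of each choice feature per switcher phenotype.
#: Phenotypes are coherent in feature space: a low switcher holds one side
#: (slope near 1, SW near 0) and its fitted softmax parameters reflect rigid
#: exploitation (high beta), while a high switcher is balanced and more
#: exploratory.
SWITCHER_PHENOTYPES: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "LS": {"a": (0.90, 0.05), "sw": (5.0, 4.0), "alpha": (0.15, 0.05), "beta": (4.0, 0.8)},
    "IS": {"a": (0.45, 0.08), "sw": (50.0, 6.0), "alpha": (0.35, 0.10), "beta": (2.0, 0.5)},
    "HS": {"a": (0.05, 0.03), "sw": (95.0, 4.0), "alpha": (0.50, 0.10), "beta": (1.0, 0.3)},
}

_FEATURE_CLIP = {"a": (0.0, 1.0), "sw": (0.0, 100.0), "alpha": (0.01, 1.0), "beta": (0.0, 100.0)}


def simulate_switcher_cohort(
    n_per_group: int = 20, seed: int = 0,
    phenotypes: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Planted switcher-phenotype cohort in (a, SW, α, β) feature space.

    Draws ``n_per_group`` mice per phenotype from Gaussian feature
    distributions around the group-typical centres (SW centred at
    5 / 50 / 95), clipped to each feature's valid range.  Returns the
    feature table and the true group index (0 = LS, 1 = IS, 2 = HS), the
    ground truth for clustering-recovery tests.
    """
    rng = np.random.default_rng(seed)
    phen = SWITCHER_PHENOTYPES if phenotypes is None else phenotypes
    rows, truth = [], []
    for g, (name, dists) in enumerate(phen.items()):
        for _ in range(n_per_group):
            row = {}
            for feat, (mu, sd) in dists.items():
                lo, hi = _FEATURE_CLIP.get(feat, (-np.inf, np.inf))
                row[feat] = float(np.clip(rng.normal(mu, sd), lo, hi))
            rows.append(row)
            truth.append(g)
    idx = [f"m{i + 1:02d}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx), np.asarray(truth)


# ---------------------------------------------------------------------------
# Spike-train simulator
# ---------------------------------------------------------------------------


@dataclass
class SpikeSimConfig:
    """Parameters of the bursty spike-train generator.

    Tonic interspike intervals are exponential with mean
    ``tonic_mean_isi_ms``, left-truncated at 161 ms so that no tonic pair
    can ever open or continue a burst; intra-burst intervals are uniform
    in ``intra_isi_ms`` (within [40, 75] ms, safely below the 80 ms onset
    criterion).  Ground-truth %SWB is therefore exact by construction.

    Two generation modes: a stochastic one (``duration_ms`` with
    ``p_burst`` per event) and an exact-count one (``n_bursts`` and
    ``n_tonic_spikes`` set, placement shuffled by the seed).
    """

    duration_ms: float = 600_000.0  # 10 min, the usual summary basis
    tonic_mean_isi_ms: float = 400.0
    p_burst: float = 0.1
    spikes_per_burst: tuple[int, int] = (2, 6)
    intra_isi_ms: tuple[float, float] = (40.0, 75.0)
    n_bursts: int | None = None
    n_tonic_spikes: int | None = None
    neuron_id: str = "sim"
    animal_id: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if not (40.0 <= self.intra_isi_ms[0] <= self.intra_isi_ms[1] < 80.0):
            raise ValueError("intra-burst ISIs must lie within [40, 80) ms")
        if self.tonic_mean_isi_ms <= 161.0:
            raise ValueError("tonic mean ISI must exceed the 161 ms truncation")
        if self.spikes_per_burst[0] < 2:
            raise ValueError("bursts need at least 2 spikes")


@dataclass
class SimulatedSpikeTrain:
    """A generated spike train with its planted burst segmentation."""

    train: SpikeTrain
    burst_ranges: list[tuple[int, int]]  #: inclusive spike-index ranges
    true_pct_swb: float


def simulate_spike_train(config: SpikeSimConfig) -> SimulatedSpikeTrain:
    """Generate a spike train with exactly known burst structure."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    trunc = 161.0

    def tonic_gap() -> float:
        return trunc + rng.exponential(cfg.tonic_mean_isi_ms - trunc)

    times: list[float] = []
    burst_ranges: list[tuple[int, int]] = []

    def emit_burst(t0: float) -> float:
        n = int(rng.integers(cfg.spikes_per_burst[0], cfg.spikes_per_burst[1] + 1))
        start = len(times)
        t = t0
        times.append(t)
        for _ in range(n - 1):
            t += rng.uniform(*cfg.intra_isi_ms)
            times.append(t)
        burst_ranges.append((start, len(times) - 1))
        return t

    if cfg.n_bursts is not None:
        n_tonic = cfg.n_tonic_spikes or 0
        kinds = np.array(["t"] * n_tonic + ["b"] * cfg.n_bursts)
        rng.shuffle(kinds)
        t = 0.0
        for kind in kinds:
            t += tonic_gap()
            if kind == "b":
                t = emit_burst(t)
            else:
                times.append(t)
        duration = t + tonic_gap()
    else:
        t = 0.0
        duration = float(cfg.duration_ms)
        while True:
            t += tonic_gap()
            if t >= duration:
                break
            if rng.random() < cfg.p_burst:
                t = emit_burst(t)
                if t >= duration:  # burst ran past the end; trim it
                    while times and times[-1] >= duration:
                        times.pop()
                    s, e = burst_ranges[-1]
                    e = len(times) - 1
                    if e <= s:
                        burst_ranges.pop()
                        if e == s:
                            times.pop()  # a 1-spike remnant is not a burst
                    else:
                        burst_ranges[-1] = (s, e)
                    t = times[-1] if times else 0.0
            else:
                times.append(t)

    arr = np.asarray(times)
    train = SpikeTrain(cfg.neuron_id, arr, max(float(duration), float(arr[-1]) + 1.0)
                       if len(arr) else float(cfg.duration_ms),
                       animal_id=cfg.animal_id)
    n_in_burst = sum(e - s + 1 for s, e in burst_ranges)
    pct = 100.0 * n_in_burst / len(arr) if len(arr) else float("nan")
    return SimulatedSpikeTrain(train, burst_ranges, pct)
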