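"""T-maze choice analysis: trial extraction, choice statistics,
softmax reinforcement-learning model fitting, behavioural profiles and
switcher-phenotype clustering.

The task is a self-initiated dynamic foraging task: a mouse enters the
maze through a gate, breaks an infrared beam in the left or right arm
(the choice), drinks, and must exit for the next trial to arm.  Bottle
contents (water / sucrose / nothing) are swapped every few days, so an
animal that tracks the best reward must keep probing both sides.

Per-animal choice sequences are summarised by four quantities:

* **SW** — the switch rate, a pure side-balance statistic mapped to
  [0, 100]: ``SW = 100 - |((n_left/n * 100) - 50) * 2|``; 100 means the
  two sides were chosen equally often, 0 means one side only.
* **a** — the slope of |cumulative left - cumulative right| against
  trial index; 1 for a never-switching animal, near 0 for a balanced one.
* **α, β** — learning rate and inverse temperature of a softmax
  reinforcement-learning model fitted to the sequence by maximum
  likelihood, with rewards R(water)=1, R(sucrose)=2, R(nothing)=0.

Clustering the four features separates low / intermediate / high
switchers (LS / IS / HS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA

__all__ = [
    "REWARD",
    "SwapSchedule",
    "extract_trials",
    "switch_rate",
    "choice_slope",
    "win_stay",
    "PBestResult",
    "p_best_aligned",
    "return_times",
    "softmax_prob",
    "update_values",
    "negative_log_likelihood",
    "RLFit",
    "fit_rl",
    "PROFILE_VARIABLES",
    "build_profiles",
    "profiles_from_data",
    "ClassPCA",
    "class_pca",
    "ClusterResult",
    "cluster_switchers",
    "rank_consistency",
]

#: reward magnitude of each bottle content
REWARD: Mapping[str, float] = {"water": 1.0, "sucrose": 2.0, "nothing": 0.0}

SIDES = ("L", "R")

TRIAL_COLUMNS = ["mouse_id", "t_entry", "t_choice", "t_exit", "side", "outcome"]


# ---------------------------------------------------------------------------
# Swap schedule & trial extraction
# ---------------------------------------------------------------------------


@dataclass
class SwapSchedule:
    """Bottle contents per side over time.

    ``entries`` is an ordered list of ``(t_start, left_content,
    right_content)``; each entry is active on the half-open interval up
    to the next entry (so a choice at exactly a swap instant sees the
    post-swap contents).  Contents are water / sucrose / nothing.
    """

    entries: Sequence[tuple[int, str, str]]

    def __post_init__(self) -> None:
        es = [(int(t), str(l), str(r)) for t, l, r in self.entries]
        if not es:
            raise ValueError("empty swap schedule")
        if any(b[0] <= a[0] for a, b in zip(es, es[1:])):
            raise ValueError("swap times must be strictly increasing")
        for _, l, r in es:
            for c in (l, r):
                if c not in REWARD:
                    raise ValueError(f"unknown bottle content {c!r}")
        self.entries = es

    def contents_at(self, t: int) -> tuple[str, str]:
        """(left, right) contents active at time ``t``."""
        times = [e[0] for e in self.entries]
        i = int(np.searchsorted(times, t, side="right")) - 1
        if i < 0:
            i = 0
        return self.entries[i][1], self.entries[i][2]

    def outcome(self, side: str, t: int) -> str:
        left, right = self.contents_at(t)
        return left if side == "L" else right

    def best_side(self, t: int) -> str | None:
        """Side with the higher-valued content, or None on a tie."""
        left, right = self.contents_at(t)
        if REWARD[left] == REWARD[right]:
            return None
        return "L" if REWARD[left] > REWARD[right] else "R"

    @property
    def swap_times(self) -> list[int]:
        return [e[0] for e in self.entries]


def extract_trials(
    events: pd.DataFrame,
    beams: Mapping[str, str],
    schedule: SwapSchedule,
    *,
    gate_sensor: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Reconstruct T-maze trials from gate and beam events.

    A trial is: gate entry (``extra == "in"``) → first beam break (the
    choice; its arm gives the side, the swap schedule the outcome) →
    gate exit (``extra == "out"``).  Entries without any beam break are
    counted as aborted and excluded; a beam break without a preceding
    open entry is an anomaly and skipped.

    Parameters
    ----------
    events
        Event table with gate and beam rows (``sensor_kind`` in
        {"gate", "beam"}).
    beams
        Mapping of beam sensor id to arm ("L"/"R"), usually
        ``topology.beams``.
    schedule
        The swap schedule used to assign outcomes at choice time.
    gate_sensor
        Restrict gate events to this sensor id (optional).

    Returns
    -------
    (trials, info)
        Trials with columns ``mouse_id, t_entry, t_choice, t_exit, side,
        outcome``, sorted per mouse; ``info`` counts aborted entries and
        orphan beam breaks.
    """
    df = events[events["sensor_kind"].isin(["gate", "beam"])]
    if gate_sensor is not None:
        df = df[(df["sensor_kind"] != "gate") | (df["sensor_id"] == gate_sensor)]
    info = {"aborted": 0, "orphan_beam": 0, "unclosed": 0}
    rows: list[tuple] = []
    for mouse, grp in df.groupby("mouse_id", sort=True):
        t_entry: int | None = None
        t_choice: int | None = None
        side: str | None = None
        for rec in grp.itertuples(index=False):
            if rec.sensor_kind == "gate" and rec.extra == "in":
                if t_entry is not None:
                    info["unclosed"] += 1  # re-entry without recorded exit
                t_entry, t_choice, side = int(rec.timestamp), None, None
            elif rec.sensor_kind == "beam":
                if t_entry is None:
                    info["orphan_beam"] += 1
                    continue
                if t_choice is None:  # only the first beam break counts
                    t_choice = int(rec.timestamp)
                    side = beams[rec.sensor_id]
            elif rec.sensor_kind == "gate" and rec.extra == "out":
                if t_entry is None:
                    continue
                if t_choice is None:
                    info["aborted"] += 1
                else:
                    rows.append(
                        (mouse, t_entry, t_choice, int(rec.timestamp), side,
                         schedule.outcome(side, t_choice))
                    )
                t_entry, t_choice, side = None, None, None
        if t_entry is not None:
            info["unclosed"] += 1
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return trials, info


# ---------------------------------------------------------------------------
# Choice statistics
# ---------------------------------------------------------------------------


def switch_rate(sides: Sequence[str]) -> float:
    """Switch rate SW in percent, from the left/right balance alone.

    ``SW = 100 - |((n_left / n_total * 100) - 50) * 2|``.  100 marks a
    mouse that chose both sides equally often, 0 one that always chose
    the same side.  Order-invariant: SW depends only on the counts.
    """
    sides = list(sides)
    if not sides:
        raise ValueError("empty choice sequence")
    n_left = sum(1 for s in sides if s == "L")
    return 100.0 - abs((n_left / len(sides) * 100.0 - 50.0) * 2.0)


def choice_slope(sides: Sequence[str]) -> float:
    """Slope *a* of |cumulative L - cumulative R| against trial index.

    A never-switching mouse accumulates imbalance one trial at a time
    (slope 1); a strict alternator stays bounded (slope ~0).  Unlike SW
    this statistic is order-sensitive.  Least squares with intercept.
    """
    s = np.asarray([1 if c == "L" else -1 for c in sides], dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 trials for a slope")
    imbalance = np.abs(np.cumsum(s))
    x = np.arange(1, len(s) + 1, dtype=float)
    return float(np.polyfit(x, imbalance, 1)[0])


def win_stay(
    trials: pd.DataFrame,
    *,
    repeat_window_s: float = 20.0,
    gap: str = "exit_to_entry",
) -> pd.DataFrame:
    """P(switch side | previous outcome) on repeated trials.

    Only *repeated* trials count: consecutive trials of the same mouse at
    most ``repeat_window_s`` apart (by default from the previous exit to
    the next entry; ``gap="entry_to_entry"`` uses entry times).  The
    probability of switching side is then estimated separately for each
    previous-outcome class — a win-stay animal rarely switches after the
    best reward but switches about half the time after missing it.

    Returns a frame ``prev_outcome, p_switch, n_pairs``; outcomes with no
    qualifying pair are simply absent (missing, not zero).
    """
    rows = []
    window_ms = repeat_window_s * 1000.0
    for _, grp in trials.groupby("mouse_id"):
        grp = grp.sort_values("t_entry")
        if gap == "exit_to_entry":
            gaps = grp["t_entry"].to_numpy()[1:] - grp["t_exit"].to_numpy()[:-1]
        elif gap == "entry_to_entry":
            gaps = np.diff(grp["t_entry"].to_numpy())
        else:
            raise ValueError(f"unknown gap mode {gap!r}")
        prev_out = grp["outcome"].to_numpy()[:-1]
        switched = grp["side"].to_numpy()[1:] != grp["side"].to_numpy()[:-1]
        ok = gaps <= window_ms
        for o, sw in zip(prev_out[ok], switched[ok]):
            rows.append((o, bool(sw)))
    if not rows:
        return pd.DataFrame(columns=["prev_outcome", "p_switch", "n_pairs"])
    df = pd.DataFrame(rows, columns=["prev_outcome", "switched"])
    out = (
        df.groupby("prev_outcome")["switched"]
        .agg(p_switch="mean", n_pairs="size")
        .reset_index()
    )
    return out


@dataclass
class PBestResult:
    """Probability of choosing the currently best-rewarded side."""

    mean_p_best: float  #: mean over the evaluated trials (NaN if best undefined)
    curve: pd.DataFrame  #: columns trial_since_swap, p_best, n
    p_left: float  #: raw side preference, reported when best is undefined
    n_trials_used: int


def p_best_aligned(
    trials: pd.DataFrame,
    schedule: SwapSchedule,
    *,
    horizon: int | None = 100,
) -> PBestResult:
    """Mean P(best side) and the post-swap tracking curve.

    The best side at any instant is the one holding the higher-valued
    content (sucrose > water > nothing).  The mean is taken over the
    first ``horizon`` trials (all trials if None); the curve aligns
    trials on the most recent swap and averages the best-side indicator
    per trial index since that swap.  When the two sides hold equal
    contents the best side is undefined and the raw side preference
    (``p_left``) is the meaningful number instead.
    """
    t = trials.sort_values(["mouse_id", "t_entry"]).reset_index(drop=True)
    if horizon is not None:
        t = t.groupby("mouse_id", sort=False).head(horizon)
    if len(t) == 0:
        raise ValueError("no trials")
    choice_t = t["t_choice"].to_numpy()
    sides = t["side"].to_numpy()
    best = np.array([schedule.best_side(int(tt)) for tt in choice_t], dtype=object)
    defined = best != None  # noqa: E711 - element-wise against None
    p_left = float(np.mean(sides == "L"))
    if not defined.any():
        return PBestResult(float("nan"), pd.DataFrame(
            columns=["trial_since_swap", "p_best", "n"]), p_left, 0)
    hit = (sides == best) & defined
    mean_p = float(hit[defined].mean())

    swap_times = np.asarray(schedule.swap_times)
    rows = []
    for _, grp in t.groupby("mouse_id", sort=False):
        ct = grp["t_choice"].to_numpy()
        gs = grp["side"].to_numpy()
        seg = np.searchsorted(swap_times, ct, side="right") - 1
        idx_since = np.zeros(len(ct), dtype=int)
        for i in range(1, len(ct)):
            idx_since[i] = idx_since[i - 1] + 1 if seg[i] == seg[i - 1] else 0
        for i in range(len(ct)):
            b = schedule.best_side(int(ct[i]))
            if b is not None:
                rows.append((idx_since[i], gs[i] == b))
    curve = (
        pd.DataFrame(rows, columns=["trial_since_swap", "hit"])
        .groupby("trial_since_swap")["hit"]
        .agg(p_best="mean", n="size")
        .reset_index()
    )
    return PBestResult(mean_p, curve, p_left, int(defined.sum()))


def return_times(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean inter-trial interval (s) conditioned on the previous outcome.

    The interval is from the previous trial's exit to the next trial's
    entry; an animal motivated to correct a miss returns faster after
    "nothing" than after a reward.
    """
    rows = []
    for _, grp in trials.groupby("mouse_id"):
        grp = grp.sort_values("t_entry")
        gaps_s = (grp["t_entry"].to_numpy()[1:] - grp["t_exit"].to_numpy()[:-1]) / 1000.0
        for o, g in zip(grp["outcome"].to_numpy()[:-1], gaps_s):
            rows.append((o, g))
    if not rows:
        return pd.DataFrame(columns=["prev_outcome", "mean_return_s", "n"])
    df = pd.DataFrame(rows, columns=["prev_outcome", "gap"])
    return (
        df.groupby("prev_outcome")["gap"]
        .agg(mean_return_s="mean", n="size")
        .reset_index()
    )


# ---------------------------------------------------------------------------
# Softmax reinforcement-learning model
# ---------------------------------------------------------------------------


def softmax_prob(values: Sequence[float], beta: float) -> np.ndarray:
    """Softmax choice probabilities ``P_i = exp(βV_i) / Σ_j exp(βV_j)``.

    β is the inverse temperature: 0 gives uniform choice regardless of
    the values, large β approaches greedy selection of the best value.
    Computed with a max shift for numerical stability.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    z = beta * np.asarray(values, dtype=float)
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def update_values(
    values: Sequence[float],
    chosen: int,
    reward: float,
    alpha: float,
    rule: str = "delta",
) -> np.ndarray:
    """Update the chosen action's value after an outcome.

    ``delta`` (default): ``V_c ← V_c + α (R − V_c)`` — the standard
    error-driven update whose fixed point is the running reward.
    ``literal``: ``V_c ← V_c + α R`` — a pure accumulator, kept available
    for comparison (it grows without bound under repeated reward).
    Unchosen values are unchanged.
    """
    v = np.array(values, dtype=float)
    if rule == "delta":
        v[chosen] += alpha * (reward - v[chosen])
    elif rule == "literal":
        v[chosen] += alpha * reward
    else:
        raise ValueError(f"unknown update rule {rule!r}")
    return v


def negative_log_likelihood(
    alpha: float,
    beta: float,
    choices: Sequence[int],
    rewards: Sequence[float],
    *,
    rule: str = "delta",
    v0: Sequence[float] = (0.0, 0.0),
) -> float:
    """Choice-by-choice negative log-likelihood of a choice sequence.

    Forward pass: at each trial the softmax probability of the realised
    choice under the current values is accumulated as ``−ln P``, then the
    values are updated with the realised reward.  Values start at ``v0``
    (default (0, 0)) and are not reset at bottle swaps — the animal is
    not told about swaps.
    """
    if rule not in ("delta", "literal"):
        raise ValueError(f"unknown update rule {rule!r}")
    c = np.asarray(choices, dtype=int)
    r = np.asarray(rewards, dtype=float)
    v = np.array(v0, dtype=float)
    nll = 0.0
    for k in range(len(c)):
        z = beta * v
        z = z - z.max()
        log_p = z[c[k]] - np.log(np.exp(z).sum())
        nll -= log_p
        if rule == "delta":
            v[c[k]] += alpha * (r[k] - v[c[k]])
        else:
            v[c[k]] += alpha * r[k]
    if not np.isfinite(nll):
        raise FloatingPointError("non-finite log-likelihood")
    return float(nll)


@dataclass
class RLFit:
    """Result of a maximum-likelihood softmax-RL fit."""

    alpha: float
    beta: float
    nll: float
    converged: bool
    rule: str
    starts: pd.DataFrame = field(repr=False, default=None)  #: multistart record
    boundary_warning: bool = False  #: β pinned at a bound (e.g. one-sided data)


ALPHA_BOUNDS = (1e-4, 1.0)
BETA_BOUNDS = (0.0, 100.0)


def fit_rl(
    choices: Sequence[int],
    rewards: Sequence[float],
    *,
    rule: str = "delta",
    v0: Sequence[float] = (0.0, 0.0),
    alpha_grid: Sequence[float] | None = None,
    beta_grid: Sequence[float] | None = None,
    n_refine: int = 3,
    min_trials: int = 20,
) -> RLFit:
    """Fit learning rate α and inverse temperature β by maximum likelihood.

    A deterministic multistart: the negative log-likelihood is evaluated
    on a coarse grid (α in {0.05…0.95}, β log-spaced in [0.1, 10]), and a
    bounded Nelder–Mead refinement is run from the ``n_refine`` best
    starts; the best refined point wins.  Bounds: α ∈ (0, 1], β ∈
    [0, 100].  Fewer than ``min_trials`` trials triggers a warning flag
    via ``boundary_warning`` if the optimum sits on a bound (β is
    unidentifiable on degenerate one-sided sequences).
    """
    c = np.asarray(choices, dtype=int)
    r = np.asarray(rewards, dtype=float)
    if alpha_grid is None:
        alpha_grid = np.linspace(0.05, 0.95, 10)
    if beta_grid is None:
        beta_grid = np.geomspace(0.1, 10.0, 7)

    def f(p: np.ndarray) -> float:
        a = float(np.clip(p[0], *ALPHA_BOUNDS))
        b = float(np.clip(p[1], *BETA_BOUNDS))
        return negative_log_likelihood(a, b, c, r, rule=rule, v0=v0)

    starts = [
        (a, b, negative_log_likelihood(a, b, c, r, rule=rule, v0=v0))
        for a in alpha_grid
        for b in beta_grid
    ]
    starts_df = pd.DataFrame(starts, columns=["alpha", "beta", "nll"])
    order = starts_df["nll"].to_numpy().argsort(kind="stable")

    best = None
    converged = False
    for i in order[:n_refine]:
        x0 = starts_df.loc[i, ["alpha", "beta"]].to_numpy(dtype=float)
        res = optimize.minimize(
            f, x0, method="Nelder-Mead",
            bounds=[ALPHA_BOUNDS, BETA_BOUNDS],
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    a_hat = float(np.clip(best.x[0], *ALPHA_BOUNDS))
    b_hat = float(np.clip(best.x[1], *BETA_BOUNDS))
    nll_hat = float(best.fun)
    # the refined optimum can never be worse than the best grid start
    i0 = int(order[0])
    if starts_df.loc[i0, "nll"] < nll_hat:
        a_hat = float(starts_df.loc[i0, "alpha"])
        b_hat = float(starts_df.loc[i0, "beta"])
        nll_hat = float(starts_df.loc[i0, "nll"])
    on_bound = (
        b_hat <= BETA_BOUNDS[0] + 1e-9
        or b_hat >= BETA_BOUNDS[1] - 1e-6
        or len(set(c.tolist())) < 2
    )
    return RLFit(
        alpha=a_hat, beta=b_hat, nll=nll_hat, converged=converged,
        rule=rule, starts=starts_df, boundary_warning=bool(on_bound),
    )


# ---------------------------------------------------------------------------
# 16-variable behavioural profile
# ---------------------------------------------------------------------------

#: the sixteen profile variables, by class
PROFILE_VARIABLES: Mapping[str, tuple[str, ...]] = {
    "activity": (
        "p_NC", "p_FC", "p_CC", "p_St", "p_T", "entropy", "events_per_day",
    ),
    "social": (
        "alone", "with_one", "with_two", "with_three_plus", "lf",
    ),
    "t_access": (
        "n_entries", "t_time_per_day", "t_time_per_entry", "inter_entry_s",
    ),
}

ALL_PROFILE_VARIABLES: tuple[str, ...] = tuple(
    v for cls in PROFILE_VARIABLES.values() for v in cls
)


def build_profiles(data: pd.DataFrame, *, zscore: bool = False) -> pd.DataFrame:
    """Validate and assemble the 16-variable per-mouse profile table.

    ``data`` must be indexed by mouse and contain every profile variable;
    a missing variable raises an error naming it.  Floor-antenna-derived
    measures (chasing) are deliberately not part of the profile.  With
    ``zscore=True`` each column is standardised across the cohort.
    """
    missing = [v for v in ALL_PROFILE_VARIABLES if v not in data.columns]
    if missing:
        raise ValueError(f"profile variables missing: {missing}")
    prof = data[list(ALL_PROFILE_VARIABLES)].astype(float).copy()
    if zscore:
        sd = prof.std(ddof=0).replace(0.0, 1.0)
        prof = (prof - prof.mean()) / sd
    return prof


def profiles_from_data(
    visits: pd.DataFrame,
    events: pd.DataFrame,
    transitions: pd.DataFrame,
    trials: pd.DataFrame,
    *,
    duration_ms: int,
    compartments: Sequence[str] = ("NC", "FC", "CC", "St", "T"),
    t_compartment: str = "T",
) -> pd.DataFrame:
    """Compute the full 16-variable profile for every mouse in a cohort.

    Convenience assembly over the activity / social / T-access layers:
    occupancy proportions and entropy from visits, tube detections per
    day from the event table, co-presence proportions and lead ratio,
    and T-maze access statistics from the trial table.
    """
    from .activity import events_per_day, occupancy_entropy, occupancy_profile
    from .social import copresence, lead_follow

    days = duration_ms / 86_400_000
    mice = sorted(visits["mouse_id"].unique())
    cop = copresence(visits).set_index("mouse_id")
    lf = lead_follow(transitions).set_index("mouse_id")
    epd = events_per_day(events, duration_ms=duration_ms)

    rows = {}
    for m in mice:
        prof = occupancy_profile(visits, m, compartments=compartments)
        row = {f"p_{c}": prof.proportions.get(c, 0.0) for c in compartments}
        row["entropy"] = occupancy_entropy(prof)
        row["events_per_day"] = float(epd.get(m, 0.0))
        tracked = cop.loc[m, "tracked_ms"]
        for col, name in [
            ("alone_ms", "alone"), ("with_one_ms", "with_one"),
            ("with_two_ms", "with_two"), ("with_three_plus_ms", "with_three_plus"),
        ]:
            row[name] = cop.loc[m, col] / tracked if tracked else float("nan")
        row["lf"] = float(lf.loc[m, "lf"]) if m in lf.index else float("nan")
        tm = trials[trials["mouse_id"] == m].sort_values("t_entry")
        n = len(tm)
        row["n_entries"] = float(n)
        in_maze_ms = float((tm["t_exit"] - tm["t_entry"]).sum())
        row["t_time_per_day"] = in_maze_ms / days / 1000.0  # s per day
        row["t_time_per_entry"] = in_maze_ms / n / 1000.0 if n else float("nan")
        if n >= 2:
            gaps = tm["t_entry"].to_numpy()[1:] - tm["t_exit"].to_numpy()[:-1]
            row["inter_entry_s"] = float(gaps.mean()) / 1000.0
        else:
            row["inter_entry_s"] = float("nan")
        rows[m] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "mouse_id"
    return build_profiles(df)


# ---------------------------------------------------------------------------
# Per-class PCA and switcher clustering
# ---------------------------------------------------------------------------


@dataclass
class ClassPCA:
    """First two principal components of one class of profile variables."""

    scores: pd.DataFrame  #: per-mouse PC1/PC2 scores
    loadings: pd.DataFrame  #: per-variable loadings (correlation circle)
    explained_variance_ratio: np.ndarray
    dropped: list[str]  #: constant columns removed before the PCA


def class_pca(profiles: pd.DataFrame, var_class: str) -> ClassPCA:
    """PCA of one standardized class of the 16-variable profile.

    ``var_class`` is one of ``activity``, ``social``, ``t_access``.
    Constant columns are dropped with a warning entry (they carry no
    variance).  The sign of each component is fixed so that the variable
    with the largest absolute loading loads positively, making scores
    reproducible across runs and library versions.
    """
    if var_class not in PROFILE_VARIABLES:
        raise ValueError(f"unknown variable class {var_class!r}")
    cols = [c for c in PROFILE_VARIABLES[var_class] if c in profiles.columns]
    X = profiles[cols].astype(float)
    sd = X.std(ddof=0)
    dropped = [c for c in cols if sd[c] == 0 or not np.isfinite(sd[c])]
    keep = [c for c in cols if c not in dropped]
    if len(keep) < 2:
        raise ValueError(f"not enough varying columns in class {var_class!r}")
    if len(profiles) < 3:
        raise ValueError("need at least 3 mice for a PCA")
    Z = (X[keep] - X[keep].mean()) / X[keep].std(ddof=0)
    n_comp = min(2, len(keep))
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(Z.to_numpy())
    loadings = pca.components_.T * np.sqrt(pca.explained_variance_)
    for j in range(n_comp):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    pc_names = [f"PC{j + 1}" for j in range(n_comp)]
    return ClassPCA(
        scores=pd.DataFrame(scores, index=profiles.index, columns=pc_names),
        loadings=pd.DataFrame(loadings, index=keep, columns=pc_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped=dropped,
    )


@dataclass
class ClusterResult:
    """Switcher-phenotype clustering of (a, SW, α, β)."""

    labels: pd.Series  #: per-mouse group name (LS/IS/HS for k=3)
    group_names: tuple[str, ...]
    scores: pd.DataFrame  #: PC scores of the standardized features
    centers: np.ndarray  #: aggregated centroids in PC space
    k: int
    seed: int


def cluster_switchers(
    features: pd.DataFrame,
    *,
    k: int = 3,
    seed: int = 0,
    n_boot: int = 50,
    feature_cols: Sequence[str] = ("a", "sw", "alpha", "beta"),
) -> ClusterResult:
    """Bagged k-means clustering of the four choice features.

    Features are standardized and projected on their principal
    components; k-means is run on ``n_boot`` bootstrap resamples, the
    pooled centroids are grouped by average-linkage hierarchical
    clustering, and every mouse is assigned to its nearest aggregated
    centroid (the bootstrap-aggregation scheme of classical bagged
    clustering).  Groups are relabelled by ascending mean SW, so for
    k = 3 the names LS < IS < HS are a labelling contract, not a claim
    about the clustering itself.
    """
    missing = [c for c in feature_cols if c not in features.columns]
    if missing:
        raise ValueError(f"feature columns missing: {missing}")
    n = len(features)
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} mice")
    X = features[list(feature_cols)].astype(float).to_numpy()
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    pca = PCA(n_components=min(Z.shape), svd_solver="full")
    S = pca.fit_transform(Z)

    rng = np.random.default_rng(seed)
    pool = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        km = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31)))
        km.fit(S[idx])
        pool.append(km.cluster_centers_)
    pool = np.vstack(pool)
    agg = AgglomerativeClustering(n_clusters=k, linkage="average").fit(pool)
    centers = np.vstack([pool[agg.labels_ == g].mean(axis=0) for g in range(k)])

    d = ((S[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    raw = d.argmin(axis=1)

    sw = features["sw"].astype(float).to_numpy()
    mean_sw = [sw[raw == g].mean() if (raw == g).any() else np.inf for g in range(k)]
    order = np.argsort(mean_sw, kind="stable")
    if k == 3:
        names = ("LS", "IS", "HS")
    else:
        names = tuple(f"G{i + 1}" for i in range(k))
    relabel = {int(g): names[rank] for rank, g in enumerate(order)}
    labels = pd.Series([relabel[int(g)] for g in raw], index=features.index, name="group")
    pc_names = [f"PC{j + 1}" for j in range(S.shape[1])]
    return ClusterResult(
        labels=labels,
        group_names=names,
        scores=pd.DataFrame(S, index=features.index, columns=pc_names),
        centers=centers[order],
        k=k,
        seed=seed,
    )


def rank_consistency(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation between paired per-mouse measurements.

    The consistency of an individual measure across two sessions: rho
    near 1 means the ranking of animals is preserved.  Ties are handled
    by midranks; fewer than 4 pairs is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired measurements must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
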