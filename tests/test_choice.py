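"""Trial extraction, choice statistics and the softmax-RL model."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colonytrack.choice import (
    REWARD,
    SwapSchedule,
    choice_slope,
    extract_trials,
    fit_rl,
    negative_log_likelihood,
    p_best_aligned,
    rank_consistency,
    return_times,
    softmax_prob,
    switch_rate,
    update_values,
    win_stay,
)
from colonytrack.simulate import ChoiceAgentConfig, simulate_choices


def _events(rows):
    return pd.DataFrame(
        rows, columns=["timestamp", "mouse_id", "sensor_id", "sensor_kind", "extra"]
    )


BEAMS = {"beam_L": "L", "beam_R": "R"}
SCHED = SwapSchedule([(0, "sucrose", "water")])


class TestExtractTrials:
    def test_hand_traced_trial(self):
        ev = _events([
            (0, "m1", "gate", "gate", "in"),
            (30_000, "m1", "beam_L", "beam", ""),
            (60_000, "m1", "gate", "gate", "out"),
        ])
        trials, info = extract_trials(ev, BEAMS, SCHED)
        assert len(trials) == 1 and info["aborted"] == 0
        row = trials.iloc[0]
        assert (row.side, row.outcome) == ("L", "sucrose")
        assert (row.t_entry, row.t_choice, row.t_exit) == (0, 30_000, 60_000)

    def test_entry_without_beam_is_aborted(self):
        ev = _events([
            (0, "m1", "gate", "gate", "in"),
            (60_000, "m1", "gate", "gate", "out"),
        ])
        trials, info = extract_trials(ev, BEAMS, SCHED)
        assert len(trials) == 0 and info["aborted"] == 1

    def test_orphan_beam_skipped(self):
        ev = _events([(5000, "m1", "beam_R", "beam", "")])
        trials, info = extract_trials(ev, BEAMS, SCHED)
        assert len(trials) == 0 and info["orphan_beam"] == 1

    def test_choice_at_swap_instant_uses_postswap_contents(self):
        sched = SwapSchedule([(0, "sucrose", "water"), (30_000, "water", "sucrose")])
        ev = _events([
            (0, "m1", "gate", "gate", "in"),
            (30_000, "m1", "beam_L", "beam", ""),  # exactly at the swap
            (60_000, "m1", "gate", "gate", "out"),
        ])
        trials, _ = extract_trials(ev, BEAMS, sched)
        assert trials.iloc[0].outcome == "water"

    def test_only_first_beam_counts(self):
        ev = _events([
            (0, "m1", "gate", "gate", "in"),
            (30_000, "m1", "beam_R", "beam", ""),
            (31_000, "m1", "beam_L", "beam", ""),
            (60_000, "m1", "gate", "gate", "out"),
        ])
        trials, _ = extract_trials(ev, BEAMS, SCHED)
        assert trials.iloc[0].side == "R"


class TestSwitchRate:
    @pytest.mark.parametrize(
        "n_left, n_right, expected",
        [(50, 50, 100.0), (100, 0, 0.0), (0, 100, 0.0), (75, 25, 50.0), (1, 3, 50.0)],
    )
    def test_values(self, n_left, n_right, expected):
        assert switch_rate(["L"] * n_left + ["R"] * n_right) == pytest.approx(expected)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            switch_rate([])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from("LR"), min_size=1, max_size=60), st.randoms())
    def test_order_invariant_and_bounded(self, sides, rnd):
        sw = switch_rate(sides)
        assert 0.0 <= sw <= 100.0
        shuffled = list(sides)
        rnd.shuffle(shuffled)
        assert switch_rate(shuffled) == pytest.approx(sw)


class TestChoiceSlope:
    def test_never_switch_is_one(self):
        assert choice_slope(["L"] * 40) == pytest.approx(1.0)
        assert choice_slope(["R"] * 40) == pytest.approx(1.0)

    def test_strict_alternation_near_zero(self):
        assert abs(choice_slope(["L", "R"] * 30)) < 0.02

    def test_matches_oracle_regression(self):
        # 80% left i.i.d.: slope approx 0.6, and exactly the brute-force
        # least-squares fit on the realized cumulative difference
        rng = np.random.default_rng(4)
        sides = ["L" if u < 0.8 else "R" for u in rng.random(400)]
        a = choice_slope(sides)
        y = np.abs(np.cumsum([1 if s == "L" else -1 for s in sides]))
        x = np.arange(1, 401)
        X = np.column_stack([x, np.ones_like(x)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert a == pytest.approx(beta[0], abs=1e-10)
        assert a == pytest.approx(0.6, abs=0.1)


def _make_trials(rows):
    return pd.DataFrame(
        rows, columns=["mouse_id", "t_entry", "t_choice", "t_exit", "side", "outcome"]
    )


class TestWinStay:
    def _trials(self, gap_ms):
        rows, t = [], 0
        outcomes = ["sucrose", "water", "sucrose", "sucrose", "water", "sucrose"]
        sides = ["L", "R", "L", "L", "R", "L"]
        for s, o in zip(sides, outcomes):
            rows.append(("m1", t, t + 1000, t + 2000, s, o))
            t += 2000 + gap_ms
        return _make_trials(rows)

    def test_perfect_win_stay_agent(self):
        rows, t = [], 0
        for _ in range(10):
            rows.append(("m1", t, t + 1000, t + 2000, "L", "sucrose"))
            t += 7000
        out = win_stay(_make_trials(rows)).set_index("prev_outcome")
        assert out.loc["sucrose", "p_switch"] == 0.0

    def test_gaps_beyond_window_yield_missing(self):
        out = win_stay(self._trials(gap_ms=25_000))
        assert len(out) == 0

    def test_random_chooser_near_half(self):
        rng = np.random.default_rng(5)
        rows, t = [], 0
        for _ in range(2000):
            s = "L" if rng.random() < 0.5 else "R"
            o = SCHED.outcome(s, t)
            rows.append(("m1", t, t + 1000, t + 2000, s, o))
            t += 7000
        out = win_stay(_make_trials(rows)).set_index("prev_outcome")
        assert out.p_switch.between(0.45, 0.55).all()


class TestPBestAligned:
    def test_omniscient_agent(self):
        sched = SwapSchedule([(0, "sucrose", "water"), (50_000, "water", "sucrose")])
        rows = []
        for k in range(100):
            t = k * 1000
            side = "L" if t < 50_000 else "R"
            rows.append(("m1", t, t, t + 500, side, sched.outcome(side, t)))
        res = p_best_aligned(_make_trials(rows), sched)
        assert res.mean_p_best == 1.0
        assert (res.curve.p_best == 1.0).all()

    def test_never_switch_agent_with_one_swap(self):
        sched = SwapSchedule([(0, "sucrose", "water"), (50_000, "water", "sucrose")])
        rows = [("m1", k * 1000, k * 1000, k * 1000 + 500, "L",
                 sched.outcome("L", k * 1000)) for k in range(100)]
        res = p_best_aligned(_make_trials(rows), sched)
        assert res.mean_p_best == pytest.approx(0.5)

    def test_equal_contents_reports_side_preference(self):
        sched = SwapSchedule([(0, "water", "water")])
        rows = [("m1", k, k, k + 1, "L", "water") for k in range(10)]
        res = p_best_aligned(_make_trials(rows), sched)
        assert math.isnan(res.mean_p_best)
        assert res.p_left == 1.0

    def test_rl_agent_postswap_curve_rises(self):
        sim = simulate_choices(
            ChoiceAgentConfig(kind="rl", alpha=0.3, beta=2.0, n_trials=600,
                              swap_every=50, seed=9)
        )
        res = p_best_aligned(sim.trials, sim.schedule, horizon=None)
        c = res.curve[res.curve.n >= 8]
        early = c[c.trial_since_swap < 5].p_best.mean()
        late = c[c.trial_since_swap.between(20, 45)].p_best.mean()
        assert late > early
        assert late > 0.5


class TestReturnTimes:
    def test_constructed_means(self):
        rows, t = [], 0
        for k in range(6):
            o = "nothing" if k % 2 == 0 else "water"
            rows.append(("m1", t, t + 1000, t + 2000, "L", o))
            t += 2000 + (10_000 if o == "nothing" else 60_000)
        out = return_times(_make_trials(rows)).set_index("prev_outcome")
        assert out.loc["nothing", "mean_return_s"] == pytest.approx(10.0)
        assert out.loc["water", "mean_return_s"] == pytest.approx(60.0)

    def test_single_trial_missing(self):
        out = return_times(_make_trials([("m1", 0, 1, 2, "L", "water")]))
        assert len(out) == 0


class TestSoftmaxAndUpdate:
    def test_symmetry_and_beta_zero(self):
        assert softmax_prob([1.0, 1.0], 5.0) == pytest.approx([0.5, 0.5])
        assert softmax_prob([3.0, -1.0], 0.0) == pytest.approx([0.5, 0.5])

    def test_closed_form(self):
        p = softmax_prob([2.0, 1.0], 1.0)
        assert p[0] == pytest.approx(0.7311, abs=1e-4)

    def test_stability_at_large_beta(self):
        p = softmax_prob([1000.0, 0.0], 100.0)
        assert np.isfinite(p).all() and p[0] == pytest.approx(1.0)

    def test_delta_update(self):
        v = update_values([0.0, 0.0], 0, 2.0, 0.5)
        assert v[0] == 1.0 and v[1] == 0.0

    def test_zero_alpha_no_change(self):
        v = update_values([0.3, 0.7], 1, 2.0, 0.0)
        assert v == pytest.approx([0.3, 0.7])

    def test_delta_fixed_point(self):
        v = np.zeros(2)
        prev_gap = 2.0
        for _ in range(50):
            v = update_values(v, 0, 2.0, 0.4)
            gap = 2.0 - v[0]
            assert 0 <= gap < prev_gap
            prev_gap = gap
        assert v[0] == pytest.approx(2.0, abs=1e-6)

    def test_literal_rule_accumulates(self):
        v = update_values([1.0, 0.0], 0, 2.0, 0.5, rule="literal")
        assert v[0] == 2.0

    def test_unknown_rule(self):
        with pytest.raises(ValueError, match="rule"):
            update_values([0, 0], 0, 1.0, 0.5, rule="bogus")


def nll_by_enumeration(alpha, beta, choices, rewards):
    """Independent oracle: -log of the sequence probability, computed
    step-by-step with plain math on scalars (no shared code path)."""
    v = [0.0, 0.0]
    logp = 0.0
    for c, r in zip(choices, rewards):
        num = math.exp(beta * v[c])
        den = math.exp(beta * v[0]) + math.exp(beta * v[1])
        logp += math.log(num / den)
        v[c] = v[c] + alpha * (r - v[c])
    return -logp


class TestNegativeLogLikelihood:
    def test_beta_zero_gives_n_log_two(self):
        c = [0, 1, 1, 0, 1]
        r = [1.0, 2.0, 0.0, 1.0, 2.0]
        assert negative_log_likelihood(0.5, 0.0, c, r) == pytest.approx(5 * math.log(2))

    def test_length_one_uniform(self):
        assert negative_log_likelihood(0.3, 2.0, [0], [2.0]) == pytest.approx(math.log(2))

    def test_six_trial_hand_sequence_matches_enumeration(self):
        c = [0, 0, 1, 0, 1, 1]
        r = [2.0, 2.0, 1.0, 0.0, 1.0, 1.0]
        got = negative_log_likelihood(0.4, 1.5, c, r)
        assert got == pytest.approx(nll_by_enumeration(0.4, 1.5, c, r), abs=1e-12)

    def test_sequence_probabilities_sum_to_one(self):
        # enumerate the full binary choice tree for a fixed outcome map
        reward_of = {0: 2.0, 1: 1.0}
        alpha, beta, n = 0.35, 1.2, 6
        total = 0.0
        for seq in itertools.product([0, 1], repeat=n):
            r = [reward_of[c] for c in seq]
            total += math.exp(-negative_log_likelihood(alpha, beta, seq, r))
        assert total == pytest.approx(1.0, abs=1e-12)


class TestFitRL:
    def test_fit_not_worse_than_any_grid_start(self):
        sim = simulate_choices(ChoiceAgentConfig(seed=2))
        c = (sim.trials.side == "R").astype(int).to_numpy()
        r = sim.trials.outcome.map(REWARD).to_numpy()
        fit = fit_rl(c, r)
        assert fit.nll <= fit.starts.nll.min() + 1e-9

    def test_random_chooser_beta_near_zero(self):
        sim = simulate_choices(ChoiceAgentConfig(kind="random", n_trials=400, seed=3))
        c = (sim.trials.side == "R").astype(int).to_numpy()
        r = sim.trials.outcome.map(REWARD).to_numpy()
        fit = fit_rl(c, r)
        assert fit.beta < 0.5

    def test_degenerate_one_sided_sequence_flagged(self):
        c = np.zeros(50, dtype=int)
        r = np.full(50, 2.0)
        fit = fit_rl(c, r)
        assert fit.boundary_warning


class TestRankConsistency:
    def test_identical_and_reversed(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert rank_consistency(x, x)[0] == pytest.approx(1.0)
        assert rank_consistency(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="at least 4"):
            rank_consistency([1, 2, 3], [3, 2, 1])

    def test_independent_sessions_near_zero(self):
        rng = np.random.default_rng(8)
        rhos = [
            rank_consistency(rng.random(30), rng.random(30))[0] for _ in range(50)
        ]
        # null rho has sd ~ 1/sqrt(29); the mean of 50 draws is near 0
        assert abs(np.mean(rhos)) < 0.1
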