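import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from banditfit.stats import (
    fraction_length1_runs,
    next_vs_prev_run,
    p_best_action,
    runs,
    stay_by_repeats_since_switch,
    stay_by_rewards_since_switch,
    stay_prob_given_reward,
)
from banditfit.task import BlockSchedule, BlockSpec, Session


def _session(actions, rewards=None, blocks=None, schedule=None):
    n = len(actions)
    return Session("s", "g", blocks or [0] * n, actions,
                   rewards or [0] * n, schedule=schedule)


class TestPBestAction:
    def test_always_best_chooser(self):
        sched = BlockSchedule((BlockSpec(0.25, 0.05, 4), BlockSpec(0.05, 0.25, 4)))
        sess = _session([0] * 4 + [1] * 4, blocks=[0] * 4 + [1] * 4,
                        schedule=sched)
        assert p_best_action(sess) == 1.0

    def test_alternating_chooser_is_half(self):
        sched = BlockSchedule((BlockSpec(0.25, 0.05, 4),))
        sess = _session([0, 1, 0, 1], schedule=sched)
        assert p_best_action(sess) == 0.5

    def test_requires_schedule(self):
        with pytest.raises(ValueError):
            p_best_action(_session([0, 1]))


class TestStayGivenReward:
    def test_perfect_perseverator(self):
        sess = _session([0] * 6, rewards=[1, 0, 1, 0, 1, 0])
        assert stay_prob_given_reward(sess) == (1.0, 1.0)

    def test_win_switch_lose_stay(self):
        sess = _session([0, 1, 1, 0], rewards=[1, 0, 1, 0])
        p_r, p_nr = stay_prob_given_reward(sess)
        assert (p_r, p_nr) == (0.0, 1.0)

    def test_hand_counted_example(self):
        # L(r=1), R, R(r=0), R -> stay|reward 0, stay|no-reward 1
        sess = _session([0, 1, 1, 1], rewards=[1, 0, 0, 0])
        assert stay_prob_given_reward(sess) == (0.0, 1.0)

    def test_pairs_do_not_cross_blocks(self):
        sess = _session([0, 0, 1, 1], rewards=[1, 1, 0, 0],
                        blocks=[0, 0, 1, 1])
        p_r, p_nr = stay_prob_given_reward(sess)
        # the rewarded L->R transition at the block boundary is excluded
        assert p_r == 1.0 and p_nr == 1.0


class TestRuns:
    def test_worked_example(self):
        rd = runs(np.array([0, 1, 1, 0]))
        assert rd.actions == (0, 1, 0)
        assert rd.lengths == (1, 2, 1)

    def test_constant_sequence_single_run(self):
        rd = runs(np.zeros(7, dtype=int))
        assert rd.lengths == (7,)

    def test_alternation_all_ones(self):
        rd = runs(np.array([0, 1] * 5))
        assert rd.lengths == (1,) * 10

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=200))
    @settings(deadline=None)
    def test_lengths_conserve_trials(self, seq):
        rd = runs(np.array(seq))
        assert rd.n_trials == len(seq)

    def test_fraction_length1(self):
        sess = _session([0, 1, 1, 0, 0, 0])
        assert fraction_length1_runs(sess) == pytest.approx(1 / 3)


class TestStayByRewardsSinceSwitch:
    def test_all_reward_perseverator_all_ones(self):
        sess = _session([0] * 8, rewards=[1] * 8)
        bins = stay_by_rewards_since_switch(sess)
        assert np.allclose(bins.dropna(), 1.0)
        assert not bins.isna().all()

    def test_no_rewarded_trials_empty(self):
        sess = _session([0] * 5, rewards=[0] * 5)
        assert stay_by_rewards_since_switch(sess).isna().all()

    def test_reward_count_excludes_current_trial(self):
        # rewards at t=0 and t=2 on one long run: t=0 falls in bin '0',
        # t=2 has exactly one earlier reward -> bin '1'
        sess = _session([0] * 4, rewards=[1, 0, 1, 0])
        bins = stay_by_rewards_since_switch(sess)
        assert bins["0"] == 1.0
        assert bins["1"] == 1.0
        assert np.isnan(bins["2"])


class TestStayByRepeats:
    def test_constant_stay_flat_at_one(self):
        sess = _session([0] * 10)
        vals = stay_by_repeats_since_switch(sess, max_repeats=5).dropna()
        assert np.allclose(vals, 1.0)

    def test_rewarded_trials_excluded_by_filter(self):
        sess = _session([0, 0, 0, 0], rewards=[0, 1, 0, 0])
        vals = stay_by_repeats_since_switch(sess, max_repeats=3)
        # trial 1 is rewarded and trials 2-3 have a reward since the switch
        assert not np.isnan(vals[0])
        assert np.isnan(vals[1]) and np.isnan(vals[2])

    def test_constant_switch_hazard_recovered(self):
        rng = np.random.default_rng(0)
        h = 0.3
        actions = [0]
        for _ in range(20000):
            actions.append(1 - actions[-1] if rng.random() < h else actions[-1])
        sess = _session(actions)
        vals = stay_by_repeats_since_switch(sess, max_repeats=5).dropna()
        assert np.allclose(vals, 1 - h, atol=0.05)


class TestNextVsPrevRun:
    def test_strict_alternation_point_one_one(self):
        sess = _session([0, 1] * 10)
        table = next_vs_prev_run([sess])
        assert table[1] == 1.0
        assert table.drop(1).isna().all()

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(3)
        actions = rng.integers(0, 2, 100)
        a = _session(actions.tolist())
        b = _session((1 - actions).tolist())
        ta, tb = next_vs_prev_run([a]), next_vs_prev_run([b])
        assert ta.fillna(-1).tolist() == tb.fillna(-1).tolist()
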