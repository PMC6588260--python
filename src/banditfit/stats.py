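"""Behavioural summary statistics.

All consecutive-pair statistics (stay probabilities, runs) are computed
within blocks only; blocks are separated by rating screens in the task, so
the first trial of a block has no "previous trial".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import Session

REWARD_BINS = ("0", "1", "2", ">2")


def p_best_action(session: Session) -> float:
    """Fraction of trials choosing the block's higher-probability action."""
    if session.schedule is None:
        raise ValueError("session has no attached schedule")
    best = np.array([session.schedule[b].better_action for b in session.blocks])
    return float((session.actions == best).mean())


def _within_block_pairs(session: Session) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(stayed, prev_reward, pair mask) for consecutive within-block trials."""
    a, r, b = session.actions, session.rewards, session.blocks
    same_block = b[1:] == b[:-1]
    stayed = (a[1:] == a[:-1])[same_block]
    prev_reward = r[:-1][same_block]
    return stayed, prev_reward, same_block


def stay_prob_given_reward(session: Session) -> tuple[float, float]:
    """(p(stay | previous rewarded), p(stay | previous unrewarded))."""
    if session.n_trials < 2:
        raise ValueError("need at least two trials")
    stayed, prev_reward, _ = _within_block_pairs(session)
    with np.errstate(invalid="ignore"):
        p_r = float(stayed[prev_reward == 1].mean()) if (prev_reward == 1).any() else np.nan
        p_nr = float(stayed[prev_reward == 0].mean()) if (prev_reward == 0).any() else np.nan
    return p_r, p_nr


@dataclass(frozen=True)
class RunDecomposition:
    """Run-length encoding of an action sequence."""

    actions: tuple[int, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(l < 1 for l in self.lengths):
            raise ValueError("run lengths must be positive")
        for a, b in zip(self.actions, self.actions[1:]):
            if a == b:
                raise ValueError("adjacent runs must differ in action")

    @property
    def n_trials(self) -> int:
        return sum(self.lengths)


def runs(actions: np.ndarray) -> RunDecomposition:
    """Run-length encode a choice sequence."""
    actions = np.asarray(actions)
    if len(actions) == 0:
        raise ValueError("empty action sequence")
    change = np.flatnonzero(np.diff(actions) != 0)
    bounds = np.concatenate([[0], change + 1, [len(actions)]])
    lengths = tuple(int(x) for x in np.diff(bounds))
    return RunDecomposition(tuple(int(actions[i]) for i in bounds[:-1]), lengths)


def _run_index_arrays(session: Session) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial (repeats since switch, rewards since switch, block-start flag).

    'Repeats since switch' is 0 on the first trial of a run; runs restart
    at block boundaries.  'Rewards since switch' counts rewards earned on
    the current run's earlier trials (excluding the current trial).
    """
    a, r, b = session.actions, session.rewards, session.blocks
    n = session.n_trials
    repeats = np.zeros(n, dtype=int)
    rewards_since = np.zeros(n, dtype=int)
    starts = session.block_starts()
    for t in range(1, n):
        if starts[t] or a[t] != a[t - 1]:
            continue
        repeats[t] = repeats[t - 1] + 1
        rewards_since[t] = rewards_since[t - 1] + r[t - 1]
    return repeats, rewards_since, starts


def _stay_indicator(session: Session) -> np.ndarray:
    """Per-trial: 1 if the next (within-block) trial repeats this action."""
    a, b = session.actions, session.blocks
    stay = np.full(session.n_trials, np.nan)
    same_block = b[1:] == b[:-1]
    stay[:-1][same_block] = (a[1:] == a[:-1])[same_block]
    return stay


def stay_by_rewards_since_switch(session: Session) -> pd.Series:
    """Stay probability after rewarded trials, binned by the number of
    rewards earned since switching to the current action (before the
    current trial): bins 0, 1, 2, >2."""
    _, rewards_since, _ = _run_index_arrays(session)
    stay = _stay_indicator(session)
    sel = (session.rewards == 1) & ~np.isnan(stay)
    binned = np.minimum(rewards_since[sel], 3)
    out = pd.Series(index=list(REWARD_BINS), dtype=float)
    for k, name in enumerate(REWARD_BINS):
        m = binned == k
        out[name] = float(stay[sel][m].mean()) if m.any() else np.nan
    return out


def stay_by_repeats_since_switch(session: Session, max_repeats: int = 15) -> pd.Series:
    """Stay probability vs number of repeats since switching (0..max).

    Includes only trials on which (i) no reward was earned on that trial
    and (ii) no reward had been earned since switching to the action.
    """
    repeats, rewards_since, _ = _run_index_arrays(session)
    stay = _stay_indicator(session)
    sel = (session.rewards == 0) & (rewards_since == 0) & ~np.isnan(stay)
    out = pd.Series(index=np.arange(max_repeats + 1), dtype=float)
    for k in range(max_repeats + 1):
        m = sel & (repeats == k)
        out[k] = float(stay[m].mean()) if m.any() else np.nan
    return out


def _session_runs_within_blocks(session: Session) -> list[RunDecomposition]:
    return [
        runs(session.actions[session.blocks == b])
        for b in np.unique(session.blocks)
    ]


def fraction_length1_runs(session: Session) -> float:
    """Fraction of within-block runs of length 1."""
    lengths = [l for rd in _session_runs_within_blocks(session) for l in rd.lengths]
    return float(np.mean(np.array(lengths) == 1))


def next_vs_prev_run(sessions: list[Session], max_prev: int = 10) -> pd.Series:
    """Median current-run length per previous-run length, averaged over
    subjects.  Index: previous run length 1..max_prev."""
    per_subject = []
    for sess in sessions:
        pairs: dict[int, list[int]] = {}
        for rd in _session_runs_within_blocks(sess):
            for prev, cur in zip(rd.lengths, rd.lengths[1:]):
                if prev <= max_prev:
                    pairs.setdefault(prev, []).append(cur)
        per_subject.append(
            pd.Series({k: float(np.median(v)) for k, v in pairs.items()})
        )
    return pd.DataFrame(per_subject).mean(axis=0).reindex(
        np.arange(1, max_prev + 1)
    )


def behaviour_table(sessions: list[Session]) -> pd.DataFrame:
    """Tidy per-subject table (subject, statistic, bin, value) of all the
    summary statistics, suitable for plotting or export."""
    rows = []
    for sess in sessions:
        sid = sess.subject_id
        if sess.schedule is not None:
            rows.append((sid, "p_best_action", "", p_best_action(sess)))
        p_r, p_nr = stay_prob_given_reward(sess)
        rows.append((sid, "stay_given_reward", "reward", p_r))
        rows.append((sid, "stay_given_reward", "no_reward", p_nr))
        for name, val in stay_by_rewards_since_switch(sess).items():
            rows.append((sid, "stay_by_rewards_since_switch", name, val))
        for k, val in stay_by_repeats_since_switch(sess).items():
            rows.append((sid, "stay_by_repeats_since_switch", str(k), val))
        rows.append((sid, "fraction_length1_runs", "", fraction_length1_runs(sess)))
    return pd.DataFrame(rows, columns=["subject_id", "statistic", "bin", "value"])
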