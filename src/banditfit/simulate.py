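"""On-policy, off-policy and mixed simulation of fitted agents.

Off-policy: a forced (action, reward) sequence is fed to a frozen agent
while only its per-trial predictions are recorded.  On-policy: the agent
acts on its own policy and receives task feedback.  Mixed: a forced
prefix followed by a self-generated continuation (greedy by default),
used to probe whether a model sustains choice oscillations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .agents.base import Agent
from .task import BlockSchedule, L, R, Session, sample_reward


@dataclass(frozen=True)
class Scenario:
    """A simulation probe: forced prefix plus optional continuation."""

    forced: tuple[tuple[int, int], ...]  # (action, reward) pairs
    n_on_policy: int = 0
    on_policy_mode: str = "greedy"

    def __post_init__(self) -> None:
        if self.n_on_policy < 0:
            raise ValueError("n_on_policy must be >= 0")
        for a, r in self.forced:
            if a not in (L, R) or r not in (0, 1):
                raise ValueError("forced entries must be (action in {0,1}, reward in {0,1})")
        if self.on_policy_mode not in ("greedy", "sample"):
            raise ValueError("on_policy_mode must be 'greedy' or 'sample'")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"trial": t, "action": "LR"[a], "reward": r, "phase": "forced"}
            for t, (a, r) in enumerate(self.forced)
        ]
        for t in range(self.n_on_policy):
            rows.append({"trial": len(self.forced) + t, "action": "",
                         "reward": 0, "phase": "on"})
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, on_policy_mode: str = "greedy") -> "Scenario":
        forced = tuple(
            ("LR".index(row.action), int(row.reward))
            for row in df.itertuples() if row.phase == "forced"
        )
        n_on = int((df["phase"] == "on").sum())
        return cls(forced, n_on, on_policy_mode)

    @classmethod
    def load(cls, path, on_policy_mode: str = "greedy") -> "Scenario":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False),
                              on_policy_mode)


def run_off_policy(agent: Agent, scenario: Scenario) -> np.ndarray:
    """Feed the forced sequence; record the policy before each trial."""
    if not scenario.forced:
        raise ValueError("off-policy scenario must contain forced trials")
    agent.reset()
    trace = np.zeros((len(scenario.forced), 2))
    for t, (a, r) in enumerate(scenario.forced):
        trace[t] = agent.predict()
        agent.observe(a, r)
    return trace


def run_mixed(agent: Agent, scenario: Scenario, seed: int = 0,
              reward_fn=None) -> tuple[np.ndarray, np.ndarray]:
    """Forced prefix, then greedy or sampled continuation.

    Continuation rewards default to 0 (probe convention); ``reward_fn``
    may supply ``f(action, rng) -> reward`` instead.  Returns the full
    policy trace and the actions fed or chosen on every trial.
    """
    rng = np.random.default_rng(seed)
    n = len(scenario.forced) + scenario.n_on_policy
    trace = np.zeros((n, 2))
    actions = np.zeros(n, dtype=np.int64)
    agent.reset()
    for t, (a, r) in enumerate(scenario.forced):
        trace[t] = agent.predict()
        actions[t] = a
        agent.observe(a, r)
    for t in range(len(scenario.forced), n):
        p = agent.predict()
        trace[t] = p
        if scenario.on_policy_mode == "greedy":
            a = int(np.argmax(p))  # ties resolve to L by index order
        else:
            a = int(rng.random() >= p[0])
        r = int(reward_fn(a, rng)) if reward_fn is not None else 0
        actions[t] = a
        agent.observe(a, r)
    return trace, actions


def run_on_policy(agent: Agent, schedule: BlockSchedule, seed: int = 0,
                  mode: str = "sample", reset_per_block: bool = True,
                  subject_id: str = "sim", group: str = "synthetic") -> Session:
    """Let the agent complete the task on its own policy."""
    rng = np.random.default_rng(seed)
    blocks, actions, rewards = [], [], []
    agent.reset()
    for b, spec in enumerate(schedule.blocks):
        if reset_per_block and b > 0:
            agent.reset()
        for _ in range(spec.n_trials):
            p = agent.predict()
            if mode == "greedy":
                a = int(np.argmax(p))
            else:
                a = int(rng.random() >= p[0])
            r = sample_reward(schedule, b, a, rng)
            agent.observe(a, r)
            blocks.append(b)
            actions.append(a)
            rewards.append(r)
    return Session(subject_id, group, np.array(blocks), np.array(actions),
                   np.array(rewards), schedule=schedule)


# --------------------------------------------------------------------------
# probe library
# --------------------------------------------------------------------------

def reward_switch_probe(reward_trials: tuple[int, ...] = (3, 6, 15)) -> Scenario:
    """30-trial probe: R for trials 0-9, then L for trials 10-29.

    Rewards are delivered on the forced action at the 0-based trial
    indices in ``reward_trials``.  The default placements are
    illustrative; vary them to probe how the switch 'dip' scales with the
    number of rewards previously earned.
    """
    forced = []
    for t in range(30):
        a = R if t < 10 else L
        forced.append((a, int(t in reward_trials)))
    return Scenario(tuple(forced), n_on_policy=0)


def oscillation_probe(n_on_policy: int = 11) -> Scenario:
    """Forced R,R,R,R,R,R,L,R,L (unrewarded) then a greedy continuation."""
    seq = [R, R, R, R, R, R, L, R, L]
    return Scenario(tuple((a, 0) for a in seq), n_on_policy=n_on_policy,
                    on_policy_mode="greedy")


def load_probe(name: str) -> Scenario:
    """Load one of the packaged probe scenario files by stem name."""
    ref = resources.files("banditfit") / "probes" / f"{name}.csv"
    with resources.as_file(ref) as path:
        return Scenario.load(path)


def stay_probability_trace(trace: np.ndarray, actions: np.ndarray) -> np.ndarray:
    """Probability assigned on each trial to repeating the previous action.

    Entry t (t >= 1) is the predicted probability at trial t of the action
    fed/taken at trial t-1; entry 0 is NaN.
    """
    out = np.full(len(actions), np.nan)
    out[1:] = trace[np.arange(1, len(actions)), actions[:-1]]
    return out
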