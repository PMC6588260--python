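"""Block-structured two-armed bandit task.

The task consists of consecutive blocks; within a block each of the two
actions (L, R) pays a binary reward with a fixed Bernoulli probability.
One action is always better than the other; across blocks the better side
and its probability vary.  The default layout is 12 blocks: better-action
probabilities {0.25, 0.125, 0.08} against a 0.05 baseline, each
(probability, side) pair appearing twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: integer codes for the two actions
L, R = 0, 1
ACTION_LABELS = ("L", "R")

DEFAULT_BETTER_PROBS = (0.25, 0.125, 0.08)
DEFAULT_BASELINE_PROB = 0.05
DEFAULT_TRIALS_PER_BLOCK = 110


def _check_prob(p: float, name: str) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {p}")


@dataclass(frozen=True)
class BlockSpec:
    """Reward probabilities and trial count for one block."""

    p_left: float
    p_right: float
    n_trials: int

    def __post_init__(self) -> None:
        _check_prob(self.p_left, "p_left")
        _check_prob(self.p_right, "p_right")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def better_action(self) -> int:
        """Index of the higher-probability action (ties -> L)."""
        return L if self.p_left >= self.p_right else R

    def p(self, action: int) -> float:
        return self.p_left if action == L else self.p_right


@dataclass(frozen=True)
class BlockSchedule:
    """Ordered sequence of blocks defining one run of the task."""

    blocks: tuple[BlockSpec, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("schedule must contain at least one block")

    def __len__(self) -> int:
        return len(self.blocks)

    def __getitem__(self, i: int) -> BlockSpec:
        return self.blocks[i]

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": np.arange(len(self.blocks)),
                "p_left": [b.p_left for b in self.blocks],
                "p_right": [b.p_right for b in self.blocks],
                "n_trials": [b.n_trials for b in self.blocks],
            }
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BlockSchedule":
        df = df.sort_values("block")
        return cls(
            tuple(
                BlockSpec(row.p_left, row.p_right, int(row.n_trials))
                for row in df.itertuples()
            )
        )

    @classmethod
    def load(cls, path) -> "BlockSchedule":
        return cls.from_frame(pd.read_csv(path))


def build_schedule(
    better_probs=DEFAULT_BETTER_PROBS,
    baseline_prob: float = DEFAULT_BASELINE_PROB,
    repeats: int = 2,
    trials_per_block=DEFAULT_TRIALS_PER_BLOCK,
    seed: int = 0,
) -> BlockSchedule:
    """Build a shuffled block schedule.

    Every (better probability, better side) pair appears ``repeats`` times,
    giving ``len(better_probs) * 2 * repeats`` blocks; the default arguments
    give the standard 12-block layout.  Block order is shuffled
    deterministically by ``seed``.  ``trials_per_block`` is either a fixed
    integer or a callable ``f(rng) -> int`` drawing a per-block count.
    """
    better_probs = list(better_probs)
    if not better_probs:
        raise ValueError("better_probs must be non-empty")
    for p in better_probs:
        _check_prob(p, "better prob")
    _check_prob(baseline_prob, "baseline_prob")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")

    rng = np.random.default_rng(seed)
    pairs = [
        (p, side) for p in better_probs for side in (L, R) for _ in range(repeats)
    ]
    order = rng.permutation(len(pairs))
    blocks = []
    for idx in order:
        p, side = pairs[idx]
        n = trials_per_block(rng) if callable(trials_per_block) else int(trials_per_block)
        if side == L:
            blocks.append(BlockSpec(p, baseline_prob, n))
        else:
            blocks.append(BlockSpec(baseline_prob, p, n))
    return BlockSchedule(tuple(blocks))


def sample_reward(schedule: BlockSchedule, block_index: int, action: int, rng) -> int:
    """Draw a binary reward for ``action`` under the block's probability."""
    if not 0 <= block_index < len(schedule):
        raise IndexError(f"block_index {block_index} out of range")
    return int(rng.random() < schedule[block_index].p(action))


@dataclass
class Session:
    """One subject's full task record.

    ``blocks``/``actions``/``rewards`` are aligned per-trial integer arrays;
    actions are coded 0 (L) / 1 (R), rewards are 0/1.  A schedule may be
    attached for statistics that need the reward layout.
    """

    subject_id: str
    group: str
    blocks: np.ndarray
    actions: np.ndarray
    rewards: np.ndarray
    schedule: BlockSchedule | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.blocks = np.asarray(self.blocks, dtype=np.int64)
        self.actions = np.asarray(self.actions, dtype=np.int64)
        self.rewards = np.asarray(self.rewards, dtype=np.int64)
        if not (len(self.blocks) == len(self.actions) == len(self.rewards)):
            raise ValueError("blocks, actions, rewards must have equal length")
        if len(self.blocks) == 0:
            raise ValueError("session must contain at least one trial")
        if np.any(np.diff(self.blocks) < 0):
            raise ValueError("block indices must be non-decreasing")
        if not np.isin(self.actions, (L, R)).all():
            raise ValueError("actions must be 0 (L) or 1 (R)")
        if not np.isin(self.rewards, (0, 1)).all():
            raise ValueError("rewards must be 0 or 1")
        if self.schedule is not None:
            counts = np.bincount(self.blocks, minlength=len(self.schedule))
            expected = [b.n_trials for b in self.schedule.blocks]
            if list(counts) != expected:
                raise ValueError("per-block trial counts do not match schedule")

    @property
    def n_trials(self) -> int:
        return len(self.actions)

    def block_starts(self) -> np.ndarray:
        """Boolean mask, True at the first trial of each block."""
        starts = np.zeros(self.n_trials, dtype=bool)
        starts[0] = True
        starts[1:] = np.diff(self.blocks) != 0
        return starts
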