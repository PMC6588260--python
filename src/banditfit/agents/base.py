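"""Common agent contract.

Every choice model — Q-learning variants, the lagged logistic regression
and the LSTM network — exposes the same strictly causal interface:

* ``reset()`` clears all internal state (called at session or block starts),
* ``predict()`` returns the probability of each action for the upcoming
  trial, using only previously observed trials,
* ``observe(action, reward)`` updates state with the trial just completed.

Higher layers (fitting, cross-validation, simulation, statistics) depend
only on this contract.
"""

from __future__ import annotations

import abc

import numpy as np


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    logits = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite logits")
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Agent(abc.ABC):
    """Strictly causal two-action choice model."""

    n_actions: int = 2

    @abc.abstractmethod
    def reset(self) -> None:
        """Clear internal state (start of a session or block)."""

    @abc.abstractmethod
    def predict(self) -> np.ndarray:
        """Probability vector over actions for the next trial."""

    @abc.abstractmethod
    def observe(self, action: int, reward: int) -> None:
        """Consume the (action, reward) of the trial just completed."""


class UniformAgent(Agent):
    """Degenerate agent assigning 0.5 to each action; testing aid."""

    def reset(self) -> None:
        pass

    def predict(self) -> np.ndarray:
        return np.array([0.5, 0.5])

    def observe(self, action: int, reward: int) -> None:
        pass
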