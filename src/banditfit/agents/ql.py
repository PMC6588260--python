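"""Q-learning family: QL, QL with perseveration (QLP), and generalised
Q-learning (GQL).

QL learns one value per action by a delta rule with learning rate phi and
chooses through a softmax with inverse temperature beta.  QLP adds a
perseveration bonus kappa for repeating the previous action.  GQL learns
``d`` values per action (learning rates Phi) plus ``d`` action-history
traces per action (learning rates Psi); the policy combines them with
weight vectors B and K and a d-by-d value-history interaction matrix C:

    logit(a) = B . Q(a) + K . H(a) + H(a)^T C Q(a)

GQL with d = 1, Psi = [1], C = 0 reproduces QLP; QLP with kappa = 0
reproduces QL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import Agent, softmax


@dataclass(frozen=True)
class QLParams:
    phi: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class QLPParams:
    phi: float
    beta: float
    kappa: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class GQLParams:
    """Generalised Q-learning parameters (4d + d^2 scalars)."""

    Phi: np.ndarray  # d value learning rates in [0, 1]
    Psi: np.ndarray  # d history learning rates in [0, 1]
    B: np.ndarray    # d value weights
    K: np.ndarray    # d history weights
    C: np.ndarray    # d x d value-history interaction weights

    def __post_init__(self) -> None:
        for name in ("Phi", "Psi", "B", "K", "C"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        d = self.d
        if d < 1:
            raise ValueError("d must be >= 1")
        for name in ("Psi", "B", "K"):
            if getattr(self, name).shape != (d,):
                raise ValueError(f"{name} must have shape ({d},)")
        if self.C.shape != (d, d):
            raise ValueError(f"C must have shape ({d}, {d})")
        for name in ("Phi", "Psi"):
            v = getattr(self, name)
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")

    @property
    def d(self) -> int:
        return self.Phi.shape[0]

    @property
    def n_params(self) -> int:
        return sum(np.asarray(getattr(self, n)).size for n in ("Phi", "Psi", "B", "K", "C"))


def count_gql_params(d: int) -> int:
    """Number of free parameters of GQL at depth d: 4d + d^2."""
    if d < 1:
        raise ValueError("d must be >= 1")
    return 4 * d + d * d


def ql_update(Q: np.ndarray, action: int, reward: float, phi: float) -> np.ndarray:
    """Delta-rule update of the taken action's value; returns a new array."""
    Q = Q.copy()
    Q[action] = (1.0 - phi) * Q[action] + phi * reward
    return Q


class QLAgent(Agent):
    """One value per action, softmax policy."""

    def __init__(self, params: QLParams):
        self.params = params
        self.reset()

    def reset(self) -> None:
        self.Q = np.zeros(2)

    def logits(self) -> np.ndarray:
        return self.params.beta * self.Q

    def predict(self) -> np.ndarray:
        return softmax(self.logits())

    def observe(self, action: int, reward: int) -> None:
        self.Q = ql_update(self.Q, action, reward, self.params.phi)


class QLPAgent(Agent):
    """QL plus a perseveration bonus for repeating the previous action."""

    def __init__(self, params: QLPParams):
        self.params = params
        self.reset()

    def reset(self) -> None:
        self.Q = np.zeros(2)
        self.last_action: int | None = None

    def logits(self) -> np.ndarray:
        logits = self.params.beta * self.Q
        if self.last_action is not None:
            logits = logits.copy()
            logits[self.last_action] += self.params.kappa
        return logits

    def predict(self) -> np.ndarray:
        return softmax(self.logits())

    def observe(self, action: int, reward: int) -> None:
        self.Q = ql_update(self.Q, action, reward, self.params.phi)
        self.last_action = action


def gql_update(
    Q: np.ndarray, H: np.ndarray, action: int, reward: float,
    Phi: np.ndarray, Psi: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One GQL state update; Q and H are (2, d) arrays, returned as copies.

    The taken action's value vector moves elementwise toward the reward;
    every action's history vector decays, the taken one toward 1.
    """
    Q = Q.copy()
    H = H.copy()
    Q[action] = (1.0 - Phi) * Q[action] + reward * Phi
    H *= 1.0 - Psi
    H[action] += Psi
    return Q, H


def gql_logits(Q: np.ndarray, H: np.ndarray, params: GQLParams) -> np.ndarray:
    """Per-action logits B.Q(a) + K.H(a) + H(a)^T C Q(a); Q, H are (2, d)."""
    return Q @ params.B + H @ params.K + np.einsum("ai,ij,aj->a", H, params.C, Q)


class GQLAgent(Agent):
    """d value traces and d history traces per action."""

    def __init__(self, params: GQLParams):
        self.params = params
        self.reset()

    def reset(self) -> None:
        d = self.params.d
        self.Q = np.zeros((2, d))
        self.H = np.zeros((2, d))

    def logits(self) -> np.ndarray:
        return gql_logits(self.Q, self.H, self.params)

    def predict(self) -> np.ndarray:
        return softmax(self.logits())

    def observe(self, action: int, reward: int) -> None:
        self.Q, self.H = gql_update(
            self.Q, self.H, action, reward, self.params.Phi, self.params.Psi
        )
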