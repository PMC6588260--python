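"""Lagged logistic-regression choice model (LIN).

The log-odds of choosing L over R on trial t is a linear function of the
previous J trials' actions, rewards and their interactions:

    log p(L)/p(R) = mu0 + sum_{j=1..J} mu_j a_{t-j} + gamma_j r_{t-j}
                                      + zeta_j a_{t-j} r_{t-j}

Coding convention (the model is invariant to it up to a sign flip of the
coefficients): actions are +1 for L and -1 for R, rewards are 0/1, and
lags reaching before the first trial of the conditioning window are 0.
By default lags do not cross block boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import deque

import numpy as np

from .base import Agent


def action_code(action: int) -> float:
    """Signed action coding: L (0) -> +1, R (1) -> -1."""
    return 1.0 if action == 0 else -1.0


@dataclass(frozen=True)
class LINParams:
    """1 + 3J free parameters; J = 0 leaves only the intercept."""

    J: int
    mu0: float
    mu: np.ndarray     # action-lag weights, length J
    gamma: np.ndarray  # reward-lag weights, length J
    zeta: np.ndarray   # interaction weights, length J

    def __post_init__(self) -> None:
        if self.J < 0:
            raise ValueError("J must be >= 0")
        for name in ("mu", "gamma", "zeta"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (self.J,):
                raise ValueError(f"{name} must have shape ({self.J},)")

    @property
    def n_params(self) -> int:
        return 1 + 3 * self.J


def lin_features(actions, rewards, J: int) -> np.ndarray:
    """Feature vector of length 3J from the trials preceding the current one.

    ``actions``/``rewards`` hold the conditioning window in chronological
    order (most recent last).  For each lag j = 1..J the triple
    (a_{t-j}, r_{t-j}, a_{t-j} * r_{t-j}) is emitted; lags preceding the
    window are zero.
    """
    feats = np.zeros(3 * J)
    n = len(actions)
    for j in range(1, J + 1):
        if j > n:
            break
        a = action_code(actions[n - j])
        r = float(rewards[n - j])
        feats[3 * (j - 1): 3 * j] = (a, r, a * r)
    return feats


def lin_logit(features: np.ndarray, params: LINParams) -> float:
    """Log-odds of L given the lag features."""
    if features.shape != (3 * params.J,):
        raise ValueError("feature length must be 3J")
    w = np.empty(3 * params.J)
    w[0::3] = params.mu
    w[1::3] = params.gamma
    w[2::3] = params.zeta
    return params.mu0 + float(features @ w)


def lin_policy(features: np.ndarray, params: LINParams) -> np.ndarray:
    """(p(L), p(R)) from the lag features."""
    z = lin_logit(features, params)
    p_left = 1.0 / (1.0 + np.exp(-z))
    return np.array([p_left, 1.0 - p_left])


class LINAgent(Agent):
    """Agent-contract wrapper keeping a within-block lag window."""

    def __init__(self, params: LINParams):
        self.params = params
        self.reset()

    def reset(self) -> None:
        self._actions: deque = deque(maxlen=max(self.params.J, 1))
        self._rewards: deque = deque(maxlen=max(self.params.J, 1))

    def predict(self) -> np.ndarray:
        feats = lin_features(list(self._actions), list(self._rewards), self.params.J)
        return lin_policy(feats, self.params)

    def observe(self, action: int, reward: int) -> None:
        self._actions.append(action)
        self._rewards.append(reward)
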