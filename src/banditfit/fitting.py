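"""Maximum-likelihood estimation of all model families.

A single model is fitted to a whole cohort by minimising the summed
negative log-likelihood of every subject's choices.  Constrained
parameters (learning rates, inverse temperature) are optimised in an
unconstrained space via logistic / exponential transforms.  The LSTM
network is fitted with Adam (with iteration checkpoints that form the
early-stopping grid); the Q-learning family defaults to L-BFGS with
analytic gradients, which converges in far fewer evaluations at 2-12
parameters; LIN is fitted by standard binomial logistic regression on its
lagged design matrix.

Analytic gradients: forward-mode sensitivities for QL/QLP/GQL (the state
is low-dimensional and each trace depends on a single learning rate), and
backpropagation through time for the LSTM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .agents import (
    GQLAgent,
    GQLParams,
    LINAgent,
    LINParams,
    QLAgent,
    QLPAgent,
    QLPParams,
    QLParams,
    RNNAgent,
    RNNParams,
    init_rnn_params,
    rnn_nll_and_grad,
)
from .agents.lin import action_code
from .task import Session

PROB_FLOOR = 1e-12
_RATE_CLIP = 1e-16

FAMILIES = ("ql", "qlp", "gql", "lin", "rnn")


# --------------------------------------------------------------------------
# cohort tensors
# --------------------------------------------------------------------------

def cohort_tensors(cohort: list[Session], reset_per_block: bool = True) -> dict:
    """Pad a cohort into (S, T) arrays of actions, rewards, resets, valid."""
    if not cohort:
        raise ValueError("cohort must be non-empty")
    S = len(cohort)
    T = max(s.n_trials for s in cohort)
    actions = np.zeros((S, T), dtype=np.int64)
    rewards = np.zeros((S, T), dtype=np.float64)
    resets = np.zeros((S, T), dtype=bool)
    valid = np.zeros((S, T), dtype=bool)
    for i, sess in enumerate(cohort):
        n = sess.n_trials
        actions[i, :n] = sess.actions
        rewards[i, :n] = sess.rewards
        valid[i, :n] = True
        if reset_per_block:
            resets[i, :n] = sess.block_starts()
        else:
            resets[i, 0] = True
    return {"actions": actions, "rewards": rewards, "resets": resets, "valid": valid}


# --------------------------------------------------------------------------
# constraint transforms
# --------------------------------------------------------------------------

def _rate(u):
    return np.clip(expit(u), _RATE_CLIP, 1.0 - _RATE_CLIP)


def _rate_inv(p):
    return logit(np.clip(p, _RATE_CLIP, 1.0 - _RATE_CLIP))


def n_unconstrained(family: str, *, d: int = 2, J: int = 18, n_cells: int = 10,
                    n_actions: int = 2) -> int:
    from .agents import count_gql_params, count_rnn_params

    if family == "ql":
        return 2
    if family == "qlp":
        return 3
    if family == "gql":
        return count_gql_params(d)
    if family == "lin":
        return 1 + 3 * J
    if family == "rnn":
        return count_rnn_params(n_cells, n_actions)
    raise ValueError(f"unknown family {family!r}")


def transform_params(family: str, u: np.ndarray, *, d: int = 2, J: int = 18,
                     n_cells: int = 10, n_actions: int = 2):
    """Map an unconstrained vector to a constrained parameter object.

    Learning rates go through the logistic function, the inverse
    temperature through the exponential; unbounded weights are passed
    through unchanged.
    """
    u = np.asarray(u, dtype=float)
    expected = n_unconstrained(family, d=d, J=J, n_cells=n_cells, n_actions=n_actions)
    if u.shape != (expected,):
        raise ValueError(f"{family} expects {expected} unconstrained values")
    if family == "ql":
        return QLParams(phi=float(_rate(u[0])), beta=float(np.exp(u[1])))
    if family == "qlp":
        return QLPParams(phi=float(_rate(u[0])), beta=float(np.exp(u[1])),
                         kappa=float(u[2]))
    if family == "gql":
        return GQLParams(
            Phi=_rate(u[0:d]),
            Psi=_rate(u[d:2 * d]),
            B=u[2 * d:3 * d].copy(),
            K=u[3 * d:4 * d].copy(),
            C=u[4 * d:].reshape(d, d).copy(),
        )
    if family == "lin":
        return LINParams(J=J, mu0=float(u[0]), mu=u[1:J + 1].copy(),
                         gamma=u[J + 1:2 * J + 1].copy(), zeta=u[2 * J + 1:].copy())
    if family == "rnn":
        return RNNParams.from_flat(u, n_cells, n_actions)
    raise ValueError(f"unknown family {family!r}")


def inverse_transform(params) -> np.ndarray:
    """Inverse of :func:`transform_params` (exact round trip)."""
    if isinstance(params, QLParams):
        return np.array([_rate_inv(params.phi), np.log(params.beta)])
    if isinstance(params, QLPParams):
        return np.array([_rate_inv(params.phi), np.log(params.beta), params.kappa])
    if isinstance(params, GQLParams):
        return np.concatenate([
            _rate_inv(params.Phi), _rate_inv(params.Psi),
            params.B, params.K, params.C.ravel(),
        ])
    if isinstance(params, LINParams):
        return np.concatenate([[params.mu0], params.mu, params.gamma, params.zeta])
    if isinstance(params, RNNParams):
        return params.flatten()
    raise TypeError(f"unknown parameter type {type(params)!r}")


# --------------------------------------------------------------------------
# negative log-likelihoods with analytic gradients (unconstrained space)
# --------------------------------------------------------------------------

def _log_sigmoid(x):
    # log sigma(x), stable for large |x|
    return -np.logaddexp(0.0, -x)


def ql_nll_grad(u: np.ndarray, data: dict) -> tuple[float, np.ndarray]:
    """QL cohort NLL and gradient wrt (u_phi, u_beta)."""
    phi, beta = float(_rate(u[0])), float(np.exp(u[1]))
    actions, rewards = data["actions"], data["rewards"]
    resets, valid = data["resets"], data["valid"]
    S, T = actions.shape
    rows = np.arange(S)

    Q = np.zeros((S, 2))
    dQ = np.zeros((S, 2))  # dQ/dphi
    nll = 0.0
    g_phi = 0.0
    g_beta = 0.0
    for t in range(T):
        r = resets[:, t]
        if r.any():
            Q[r] = 0.0
            dQ[r] = 0.0
        a = actions[:, t]
        v = valid[:, t]
        sign = 1.0 - 2.0 * a  # +1 if L taken, -1 if R taken
        m = sign * (Q[:, 0] - Q[:, 1])
        x = beta * m
        nll -= float((_log_sigmoid(x) * v).sum())
        gx = (expit(x) - 1.0) * v
        g_beta += float((gx * m).sum())
        g_phi += float((gx * beta * sign * (dQ[:, 0] - dQ[:, 1])).sum())
        # state update for valid trials
        q_old = Q[rows, a]
        Q[rows, a] = np.where(v, (1 - phi) * q_old + phi * rewards[:, t], q_old)
        dq_old = dQ[rows, a]
        dQ[rows, a] = np.where(v, (1 - phi) * dq_old + (rewards[:, t] - q_old), dq_old)
    grad = np.array([g_phi * phi * (1 - phi), g_beta * beta])
    return nll, grad


def qlp_nll_grad(u: np.ndarray, data: dict) -> tuple[float, np.ndarray]:
    """QLP cohort NLL and gradient wrt (u_phi, u_beta, kappa)."""
    phi, beta, kappa = float(_rate(u[0])), float(np.exp(u[1])), float(u[2])
    actions, rewards = data["actions"], data["rewards"]
    resets, valid = data["resets"], data["valid"]
    S, T = actions.shape
    rows = np.arange(S)

    Q = np.zeros((S, 2))
    dQ = np.zeros((S, 2))
    last = np.full(S, -1)
    nll = 0.0
    g_phi = g_beta = g_kappa = 0.0
    for t in range(T):
        r = resets[:, t]
        if r.any():
            Q[r] = 0.0
            dQ[r] = 0.0
            last[r] = -1
        a = actions[:, t]
        v = valid[:, t]
        sign = 1.0 - 2.0 * a
        m = sign * (Q[:, 0] - Q[:, 1])
        # perseveration contrast: +1 if last == taken, -1 if last == other
        e = np.where(last < 0, 0.0, np.where(last == a, 1.0, -1.0))
        x = beta * m + kappa * e
        nll -= float((_log_sigmoid(x) * v).sum())
        gx = (expit(x) - 1.0) * v
        g_beta += float((gx * m).sum())
        g_kappa += float((gx * e).sum())
        g_phi += float((gx * beta * sign * (dQ[:, 0] - dQ[:, 1])).sum())
        q_old = Q[rows, a]
        Q[rows, a] = np.where(v, (1 - phi) * q_old + phi * rewards[:, t], q_old)
        dq_old = dQ[rows, a]
        dQ[rows, a] = np.where(v, (1 - phi) * dq_old + (rewards[:, t] - q_old), dq_old)
        last = np.where(v, a, last)
    grad = np.array([g_phi * phi * (1 - phi), g_beta * beta, g_kappa])
    return nll, grad


def gql_nll_grad(u: np.ndarray, data: dict, d: int) -> tuple[float, np.ndarray]:
    """GQL cohort NLL and gradient wrt the 4d + d^2 unconstrained values.

    Layout of ``u``: [u_Phi (d), u_Psi (d), B (d), K (d), C (d*d)].
    Forward-mode sensitivities: trace i of Q depends only on Phi_i and
    trace i of H only on Psi_i, so a single (S, 2, d) array per block of
    rates carries all state derivatives.
    """
    Phi = _rate(u[0:d])
    Psi = _rate(u[d:2 * d])
    B = u[2 * d:3 * d]
    K = u[3 * d:4 * d]
    C = u[4 * d:].reshape(d, d)
    actions, rewards = data["actions"], data["rewards"]
    resets, valid = data["resets"], data["valid"]
    S, T = actions.shape
    rows = np.arange(S)

    Q = np.zeros((S, 2, d))
    H = np.zeros((S, 2, d))
    dQ = np.zeros((S, 2, d))  # dQ_i / dPhi_i
    dH = np.zeros((S, 2, d))  # dH_i / dPsi_i
    nll = 0.0
    gPhi = np.zeros(d)
    gPsi = np.zeros(d)
    gB = np.zeros(d)
    gK = np.zeros(d)
    gC = np.zeros((d, d))
    for t in range(T):
        rs = resets[:, t]
        if rs.any():
            Q[rs] = 0.0
            H[rs] = 0.0
            dQ[rs] = 0.0
            dH[rs] = 0.0
        a = actions[:, t]
        v = valid[:, t]
        Qt, Qo = Q[rows, a], Q[rows, 1 - a]            # (S, d)
        Ht, Ho = H[rows, a], H[rows, 1 - a]
        x = (
            (Qt - Qo) @ B + (Ht - Ho) @ K
            + np.einsum("si,ij,sj->s", Ht, C, Qt)
            - np.einsum("si,ij,sj->s", Ho, C, Qo)
        )
        nll -= float((_log_sigmoid(x) * v).sum())
        gx = (expit(x) - 1.0) * v                      # (S,)
        gB += gx @ (Qt - Qo)
        gK += gx @ (Ht - Ho)
        gC += np.einsum("s,si,sj->ij", gx, Ht, Qt) - np.einsum(
            "s,si,sj->ij", gx, Ho, Qo
        )
        # through the value traces: dlogit(a)/dQ_{a,i} = B_i + (H_a C)_i
        wQt = B + Ht @ C
        wQo = B + Ho @ C
        gPhi += gx @ (wQt * dQ[rows, a] - wQo * dQ[rows, 1 - a])
        # through the history traces: dlogit(a)/dH_{a,i} = K_i + (C Q_a)_i
        wHt = K + Qt @ C.T
        wHo = K + Qo @ C.T
        gPsi += gx @ (wHt * dH[rows, a] - wHo * dH[rows, 1 - a])
        # state updates (valid trials only)
        vv = v[:, None]
        q_old = Q[rows, a]
        Q[rows, a] = np.where(vv, (1 - Phi) * q_old + rewards[:, t][:, None] * Phi, q_old)
        dq_old = dQ[rows, a]
        dQ[rows, a] = np.where(
            vv, (1 - Phi) * dq_old + (rewards[:, t][:, None] - q_old), dq_old
        )
        h_old = H.copy()
        dh_old = dH.copy()
        H = np.where(valid[:, t][:, None, None], (1 - Psi) * h_old, h_old)
        H[rows, a] += np.where(vv, Psi, 0.0)
        dH = np.where(valid[:, t][:, None, None], (1 - Psi) * dh_old - h_old, dh_old)
        dH[rows, a] += np.where(vv, 1.0, 0.0)
    grad = np.concatenate([
        gPhi * Phi * (1 - Phi), gPsi * Psi * (1 - Psi), gB, gK, gC.ravel()
    ])
    return nll, grad


def family_nll_grad(family: str, u: np.ndarray, data: dict, *, d: int = 2,
                    n_cells: int = 10, n_actions: int = 2) -> tuple[float, np.ndarray]:
    """Dispatch to the family's analytic NLL/gradient in unconstrained space."""
    if family == "ql":
        return ql_nll_grad(u, data)
    if family == "qlp":
        return qlp_nll_grad(u, data)
    if family == "gql":
        return gql_nll_grad(u, data, d)
    if family == "rnn":
        return rnn_nll_and_grad(
            u, data["actions"], data["rewards"].astype(float), data["resets"],
            data["valid"], n_cells, n_actions,
        )
    raise ValueError(f"no gradient objective for family {family!r}")


# --------------------------------------------------------------------------
# agents and cohort NLL from constrained parameters
# --------------------------------------------------------------------------

def make_agent(family: str, params):
    if family == "ql":
        return QLAgent(params)
    if family == "qlp":
        return QLPAgent(params)
    if family == "gql":
        return GQLAgent(params)
    if family == "lin":
        return LINAgent(params)
    if family == "rnn":
        return RNNAgent(params)
    raise ValueError(f"unknown family {family!r}")


def session_policies(family: str, params, session: Session,
                     reset_per_block: bool = True) -> np.ndarray:
    """Causal per-trial policy trace (T, 2) of a model over a session."""
    agent = make_agent(family, params)
    starts = session.block_starts() if reset_per_block else None
    out = np.zeros((session.n_trials, 2))
    agent.reset()
    for t in range(session.n_trials):
        if reset_per_block and t > 0 and starts[t]:
            agent.reset()
        out[t] = agent.predict()
        agent.observe(int(session.actions[t]), int(session.rewards[t]))
    return out


def cohort_negative_log_likelihood(family: str, params, cohort: list[Session],
                                   reset_per_block: bool = True) -> float:
    """Summed -log pi_t(a_t) over all subjects and trials (floored at 1e-12)."""
    if not cohort:
        raise ValueError("cohort must be non-empty")
    total = 0.0
    for sess in cohort:
        probs = session_policies(family, params, sess, reset_per_block)
        taken = probs[np.arange(sess.n_trials), sess.actions]
        total -= float(np.log(np.clip(taken, PROB_FLOOR, None)).sum())
    return total


# --------------------------------------------------------------------------
# optimisers
# --------------------------------------------------------------------------

def adam(fun: Callable, u0: np.ndarray, step_size: float = 0.01,
         max_iterations: int = 2000, checkpoint_every: int = 100,
         beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
    """Plain full-batch Adam; returns (u, history, checkpoints).

    ``checkpoints`` maps iteration -> parameter snapshot, the grid used for
    early stopping.  ``history`` is the per-iteration objective value.
    """
    u = np.asarray(u0, dtype=float).copy()
    m = np.zeros_like(u)
    s = np.zeros_like(u)
    history = []
    checkpoints: dict[int, np.ndarray] = {}
    for it in range(1, max_iterations + 1):
        val, grad = fun(u)
        if not np.isfinite(val) or not np.all(np.isfinite(grad)):
            raise FloatingPointError(f"objective diverged at iteration {it}")
        history.append(val)
        m = beta1 * m + (1 - beta1) * grad
        s = beta2 * s + (1 - beta2) * grad * grad
        mhat = m / (1 - beta1 ** it)
        shat = s / (1 - beta2 ** it)
        u -= step_size * mhat / (np.sqrt(shat) + eps)
        if it % checkpoint_every == 0:
            checkpoints[it] = u.copy()
    return u, history, checkpoints


# --------------------------------------------------------------------------
# fit_ml
# --------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Optimisation settings; ``optimizer=None`` picks the family default
    (Adam for the LSTM, L-BFGS for the Q-learning family)."""

    optimizer: str | None = None
    step_size: float = 0.01
    max_iterations: int = 2000
    checkpoint_every: int = 100
    seed: int = 0
    reset_per_block: bool = True
    n_restarts: int = 5
    rnn_init_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class FittedModel:
    """Result of a maximum-likelihood fit of one family to one cohort."""

    family: str
    params: object
    train_nll: float
    checkpoints: dict[int, object] = field(default_factory=dict)
    config: FitConfig | None = None
    hyper: dict = field(default_factory=dict)

    def agent(self):
        return make_agent(self.family, self.params)

    def policy_trace(self, session: Session) -> np.ndarray:
        rpb = self.config.reset_per_block if self.config else True
        return session_policies(self.family, self.params, session, rpb)


def _rnn_init_seed(n_cells: int) -> int:
    # one fixed initial network per architecture size, reused across fits
    return 10_000 + n_cells


def fit_ml(family: str, cohort: list[Session], config: FitConfig | None = None, *,
           d: int = 2, J: int = 18, n_cells: int = 10,
           n_actions: int = 2) -> FittedModel:
    """Fit one model family to a cohort by maximum likelihood."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if not cohort:
        raise ValueError("cohort must be non-empty")
    config = config or FitConfig()
    hyper = {"d": d, "J": J, "n_cells": n_cells, "n_actions": n_actions}

    if family == "lin":
        return _fit_lin(cohort, config, J)

    data = cohort_tensors(cohort, config.reset_per_block)
    fun = lambda u: family_nll_grad(family, u, data, d=d, n_cells=n_cells,
                                    n_actions=n_actions)
    optimizer = config.optimizer or ("adam" if family == "rnn" else "lbfgs")
    n_restarts = 1 if family == "rnn" else max(config.n_restarts, 1)
    rng = np.random.default_rng(config.seed)

    best = None
    for k in range(n_restarts):
        if family == "rnn":
            u0 = init_rnn_params(
                n_cells, n_actions, seed=_rnn_init_seed(n_cells),
                scale=config.rnn_init_scale,
            ).flatten()
        else:
            u0 = rng.normal(0.0, 1.0, n_unconstrained(family, d=d, n_cells=n_cells))
        if optimizer == "adam":
            u, history, raw_ckpts = adam(
                fun, u0, config.step_size, config.max_iterations,
                config.checkpoint_every,
            )
            final_nll = fun(u)[0]
        elif optimizer == "lbfgs":
            raw_ckpts = {}
            counter = {"it": 0}

            def _cb(xk):
                counter["it"] += 1
                if counter["it"] % config.checkpoint_every == 0:
                    raw_ckpts[counter["it"]] = xk.copy()

            res = minimize(fun, u0, jac=True, method="L-BFGS-B",
                           callback=_cb,
                           options={"maxiter": config.max_iterations})
            u, final_nll = res.x, float(res.fun)
        else:
            raise ValueError(f"unknown optimizer {optimizer!r}")
        if not np.isfinite(final_nll):
            raise FloatingPointError("fit diverged to a non-finite NLL")
        if best is None or final_nll < best[1]:
            best = (u, final_nll, raw_ckpts)

    u, final_nll, raw_ckpts = best
    to_params = lambda vec: transform_params(family, vec, d=d, J=J,
                                             n_cells=n_cells, n_actions=n_actions)
    return FittedModel(
        family=family,
        params=to_params(u),
        train_nll=final_nll,
        checkpoints={it: to_params(vec) for it, vec in raw_ckpts.items()},
        config=config,
        hyper=hyper,
    )


def _fit_lin(cohort: list[Session], config: FitConfig, J: int) -> FittedModel:
    """Binomial logistic regression on the lagged design matrix."""
    X, y = lin_design_matrix(cohort, J, config.reset_per_block)
    if J == 0:
        # intercept-only: closed-form MLE on the empirical rate (capped)
        p = float(np.clip(y.mean(), _RATE_CLIP, 1 - _RATE_CLIP))
        mu0 = float(logit(p))
        params = LINParams(J=0, mu0=mu0, mu=np.zeros(0), gamma=np.zeros(0),
                           zeta=np.zeros(0))
    else:
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000,
                                 tol=1e-8)
        clf.fit(X, y)
        w = clf.coef_[0]
        params = LINParams(J=J, mu0=float(clf.intercept_[0]),
                           mu=w[0::3].copy(), gamma=w[1::3].copy(),
                           zeta=w[2::3].copy())
    nll = cohort_negative_log_likelihood("lin", params, cohort,
                                         config.reset_per_block)
    return FittedModel(family="lin", params=params, train_nll=nll,
                       config=config, hyper={"J": J})


def lin_design_matrix(cohort: list[Session], J: int,
                      reset_per_block: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Stacked lag features (n_trials, 3J) and L-choice indicator target.

    Column order per lag j = 1..J: (a_{t-j}, r_{t-j}, a_{t-j} r_{t-j}) with
    the signed action coding; lags never cross block boundaries when
    ``reset_per_block`` is set.
    """
    rows_X, rows_y = [], []
    for sess in cohort:
        a_sig = np.array([action_code(a) for a in sess.actions])
        r = sess.rewards.astype(float)
        starts = sess.block_starts()
        seg_id = np.cumsum(starts) if reset_per_block else np.ones(sess.n_trials)
        X = np.zeros((sess.n_trials, 3 * J))
        for j in range(1, J + 1):
            ok = np.arange(sess.n_trials) >= j
            same = np.zeros(sess.n_trials, dtype=bool)
            same[j:] = seg_id[j:] == seg_id[:-j]
            use = ok & same
            X[use, 3 * (j - 1)] = a_sig[np.flatnonzero(use) - j]
            X[use, 3 * (j - 1) + 1] = r[np.flatnonzero(use) - j]
            X[use, 3 * (j - 1) + 2] = (
                a_sig[np.flatnonzero(use) - j] * r[np.flatnonzero(use) - j]
            )
        rows_X.append(X)
        rows_y.append((sess.actions == 0).astype(int))  # 1 = chose L
    return np.vstack(rows_X), np.concatenate(rows_y)
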