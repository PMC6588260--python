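"""LSTM imitation network.

A single LSTM layer followed by a bias-free softmax readout.  The input on
each trial is the one-hot previous action concatenated with the previous
binary reward (dimension N_a + 1); the first trial after a reset feeds the
zero vector.  Cell states and outputs start at zero.  Update rules:

    f_t = sigmoid(W_f x_t + U_f h_{t-1} + b_f)
    i_t = sigmoid(W_i x_t + U_i h_{t-1} + b_i)
    o_t = sigmoid(W_o x_t + U_o h_{t-1} + b_o)
    c_t = f_t * c_{t-1} + i_t * tanh(W_c x_t + U_c h_{t-1} + b_c)
    h_t = o_t * tanh(c_t)
    policy_t = softmax(V^T h_t)

Gradients of the cohort negative log-likelihood are computed by
backpropagation through time (numpy implementation, checked against
central finite differences in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import Agent, softmax

_GATES = ("f", "i", "o", "c")


def count_rnn_params(n_cells: int, n_actions: int = 2) -> int:
    """Total scalar parameter count: 4(N_c(N_a+1) + N_c^2 + N_c) + N_c N_a."""
    if n_cells < 1 or n_actions < 1:
        raise ValueError("n_cells and n_actions must be >= 1")
    n_in = n_actions + 1
    return 4 * (n_cells * n_in + n_cells * n_cells + n_cells) + n_cells * n_actions


def param_shapes(n_cells: int, n_actions: int = 2) -> list[tuple[str, tuple[int, ...]]]:
    """Fixed (name, shape) layout used for flattening parameter vectors."""
    n_in = n_actions + 1
    shapes: list[tuple[str, tuple[int, ...]]] = []
    for g in _GATES:
        shapes.append((f"W_{g}", (n_cells, n_in)))
    for g in _GATES:
        shapes.append((f"U_{g}", (n_cells, n_cells)))
    for g in _GATES:
        shapes.append((f"b_{g}", (n_cells,)))
    shapes.append(("V", (n_cells, n_actions)))
    return shapes


@dataclass
class RNNParams:
    """Named weight arrays of the LSTM layer plus the softmax readout V."""

    weights: dict[str, np.ndarray]
    n_cells: int
    n_actions: int = 2

    def __post_init__(self) -> None:
        expected = dict(param_shapes(self.n_cells, self.n_actions))
        if set(self.weights) != set(expected):
            raise ValueError("unexpected weight names")
        for name, shape in expected.items():
            w = np.asarray(self.weights[name], dtype=float)
            if w.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {w.shape}")
            self.weights[name] = w

    def __getitem__(self, name: str) -> np.ndarray:
        return self.weights[name]

    @property
    def n_params(self) -> int:
        return sum(w.size for w in self.weights.values())

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [self.weights[n].ravel() for n, _ in param_shapes(self.n_cells, self.n_actions)]
        )

    @classmethod
    def from_flat(cls, vec: np.ndarray, n_cells: int, n_actions: int = 2) -> "RNNParams":
        shapes = param_shapes(n_cells, n_actions)
        total = sum(int(np.prod(s)) for _, s in shapes)
        if vec.shape != (total,):
            raise ValueError(f"expected flat vector of length {total}")
        weights = {}
        pos = 0
        for name, shape in shapes:
            size = int(np.prod(shape))
            weights[name] = vec[pos: pos + size].reshape(shape).copy()
            pos += size
        return cls(weights, n_cells, n_actions)

    def save(self, path) -> None:
        np.savez(path, n_cells=self.n_cells, n_actions=self.n_actions, **self.weights)

    @classmethod
    def load(cls, path) -> "RNNParams":
        with np.load(path) as f:
            n_cells = int(f["n_cells"])
            n_actions = int(f["n_actions"])
            weights = {n: f[n] for n, _ in param_shapes(n_cells, n_actions)}
        return cls(weights, n_cells, n_actions)


def init_rnn_params(
    n_cells: int, n_actions: int = 2, seed: int = 0, scale: float = 0.1
) -> RNNParams:
    """Seeded uniform(-scale, scale) initialisation of all weights.

    One fixed seed per network size gives a single reusable initial
    network, so repeated fits of the same architecture start identically.
    """
    rng = np.random.default_rng(seed)
    weights = {
        name: rng.uniform(-scale, scale, size=shape)
        for name, shape in param_shapes(n_cells, n_actions)
    }
    return RNNParams(weights, n_cells, n_actions)


def encode_input(prev_action: int | None, prev_reward: int, n_actions: int = 2) -> np.ndarray:
    """One-hot previous action plus reward scalar; zeros before any trial."""
    x = np.zeros(n_actions + 1)
    if prev_action is not None:
        x[prev_action] = 1.0
        x[n_actions] = float(prev_reward)
    return x


def lstm_step(
    x: np.ndarray, h: np.ndarray, c: np.ndarray, p: RNNParams
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM update; returns (h_new, c_new)."""
    f = _sigmoid(p["W_f"] @ x + p["U_f"] @ h + p["b_f"])
    i = _sigmoid(p["W_i"] @ x + p["U_i"] @ h + p["b_i"])
    o = _sigmoid(p["W_o"] @ x + p["U_o"] @ h + p["b_o"])
    g = np.tanh(p["W_c"] @ x + p["U_c"] @ h + p["b_c"])
    c_new = f * c + i * g
    h_new = o * np.tanh(c_new)
    return h_new, c_new


def rnn_policy(h: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Softmax over V^T h (no output bias)."""
    return softmax(h @ V)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class RNNAgent(Agent):
    """Agent-contract wrapper around the LSTM network."""

    def __init__(self, params: RNNParams):
        self.params = params
        self.n_actions = params.n_actions
        self.reset()

    def reset(self) -> None:
        self.h = np.zeros(self.params.n_cells)
        self.c = np.zeros(self.params.n_cells)
        # first prediction after a reset consumes the zero input vector
        self.h, self.c = lstm_step(
            np.zeros(self.n_actions + 1), self.h, self.c, self.params
        )

    def predict(self) -> np.ndarray:
        return rnn_policy(self.h, self.params["V"])

    def observe(self, action: int, reward: int) -> None:
        x = encode_input(action, reward, self.n_actions)
        self.h, self.c = lstm_step(x, self.h, self.c, self.params)


def forward_policies(
    params: RNNParams,
    actions: np.ndarray,
    rewards: np.ndarray,
    resets: np.ndarray,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Batched causal policy computation.

    ``actions``/``rewards`` are (S, T) integer arrays, ``resets`` a (S, T)
    boolean mask marking trials at which state is cleared before
    prediction.  Returns (S, T, N_a) probabilities; prediction at trial t
    uses only trials < t.
    """
    S, T = actions.shape
    Nc, Na = params.n_cells, params.n_actions
    if valid is None:
        valid = np.ones((S, T), dtype=bool)
    h = np.zeros((S, Nc))
    c = np.zeros((S, Nc))
    V = params["V"]
    out = np.zeros((S, T, Na))
    x = np.zeros((S, Na + 1))
    for t in range(T):
        r = resets[:, t]
        if r.any():
            h[r] = 0.0
            c[r] = 0.0
            x[r] = 0.0
        h, c = _batched_step(x, h, c, params)
        out[:, t] = softmax(h @ V)
        # input for the next trial: this trial's action and reward
        x = np.zeros((S, Na + 1))
        x[np.arange(S), actions[:, t]] = 1.0
        x[:, Na] = rewards[:, t]
        x[~valid[:, t]] = 0.0
    return out


def _batched_step(x, h, c, p: RNNParams):
    f = _sigmoid(x @ p["W_f"].T + h @ p["U_f"].T + p["b_f"])
    i = _sigmoid(x @ p["W_i"].T + h @ p["U_i"].T + p["b_i"])
    o = _sigmoid(x @ p["W_o"].T + h @ p["U_o"].T + p["b_o"])
    g = np.tanh(x @ p["W_c"].T + h @ p["U_c"].T + p["b_c"])
    c_new = f * c + i * g
    h_new = o * np.tanh(c_new)
    return h_new, c_new


def rnn_nll_and_grad(
    flat: np.ndarray,
    actions: np.ndarray,
    rewards: np.ndarray,
    resets: np.ndarray,
    valid: np.ndarray,
    n_cells: int,
    n_actions: int = 2,
) -> tuple[float, np.ndarray]:
    """Cohort negative log-likelihood and its gradient (BPTT).

    Inputs are padded (S, T) arrays; ``valid`` masks padding.  The
    likelihood sums -log pi_t(a_t) over valid trials.
    """
    p = RNNParams.from_flat(flat, n_cells, n_actions)
    S, T = actions.shape
    Nc, Na = n_cells, n_actions
    V = p["V"]

    # ---- forward, storing per-step activations ----
    xs = np.zeros((T, S, Na + 1))
    h_prev = np.zeros((T, S, Nc))
    c_prev = np.zeros((T, S, Nc))
    fs = np.zeros((T, S, Nc))
    is_ = np.zeros((T, S, Nc))
    os_ = np.zeros((T, S, Nc))
    gs = np.zeros((T, S, Nc))
    tanh_cs = np.zeros((T, S, Nc))
    probs = np.zeros((T, S, Na))

    h = np.zeros((S, Nc))
    c = np.zeros((S, Nc))
    x = np.zeros((S, Na + 1))
    for t in range(T):
        r = resets[:, t]
        if r.any():
            h = h.copy(); c = c.copy(); x = x.copy()
            h[r] = 0.0; c[r] = 0.0; x[r] = 0.0
        xs[t] = x
        h_prev[t] = h
        c_prev[t] = c
        f, i, o, g, c, tanh_c, h = _batched_step_full(x, h, c, p)
        fs[t], is_[t], os_[t], gs[t], tanh_cs[t] = f, i, o, g, tanh_c
        probs[t] = softmax(h @ V)
        x = np.zeros((S, Na + 1))
        x[np.arange(S), actions[:, t]] = 1.0
        x[:, Na] = rewards[:, t]
        x[~valid[:, t]] = 0.0

    taken = probs[np.arange(T)[:, None], np.arange(S)[None, :], actions.T]
    taken = np.clip(taken, 1e-12, None)
    nll = float(-(np.log(taken) * valid.T).sum())

    # ---- backward ----
    grads = {name: np.zeros(shape) for name, shape in param_shapes(Nc, Na)}
    dh_next = np.zeros((S, Nc))
    dc_next = np.zeros((S, Nc))
    eye = np.eye(Na)
    for t in range(T - 1, -1, -1):
        dlogits = (probs[t] - eye[actions[:, t]]) * valid[:, t][:, None]
        h_t = os_[t] * tanh_cs[t]
        grads["V"] += h_t.T @ dlogits
        dh = dlogits @ V.T + dh_next
        do = dh * tanh_cs[t]
        dc = dh * os_[t] * (1.0 - tanh_cs[t] ** 2) + dc_next
        df = dc * c_prev[t]
        di = dc * gs[t]
        dg = dc * is_[t]
        dc_prev_t = dc * fs[t]
        da = {
            "f": df * fs[t] * (1.0 - fs[t]),
            "i": di * is_[t] * (1.0 - is_[t]),
            "o": do * os_[t] * (1.0 - os_[t]),
            "c": dg * (1.0 - gs[t] ** 2),
        }
        dh_prev_t = np.zeros((S, Nc))
        for g_name, d in da.items():
            grads[f"W_{g_name}"] += d.T @ xs[t]
            grads[f"U_{g_name}"] += d.T @ h_prev[t]
            grads[f"b_{g_name}"] += d.sum(axis=0)
            dh_prev_t += d @ p[f"U_{g_name}"]
        keep = ~resets[:, t]
        dh_next = dh_prev_t * keep[:, None]
        dc_next = dc_prev_t * keep[:, None]

    flat_grad = np.concatenate(
        [grads[n].ravel() for n, _ in param_shapes(Nc, Na)]
    )
    return nll, flat_grad


def _batched_step_full(x, h, c, p: RNNParams):
    f = _sigmoid(x @ p["W_f"].T + h @ p["U_f"].T + p["b_f"])
    i = _sigmoid(x @ p["W_i"].T + h @ p["U_i"].T + p["b_i"])
    o = _sigmoid(x @ p["W_o"].T + h @ p["U_o"].T + p["b_o"])
    g = np.tanh(x @ p["W_c"].T + h @ p["U_c"].T + p["b_c"])
    c_new = f * c + i * g
    tanh_c = np.tanh(c_new)
    h_new = o * tanh_c
    return f, i, o, g, c_new, tanh_c, h_new
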