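"""Session and configuration file formats.

Sessions are stored as comma-delimited text with header
``subject_id,group,block,trial,action,reward``; actions are the literal
symbols L/R.  Round-tripping a cohort through write/read is an identity.
Run configurations are YAML mappings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .task import ACTION_LABELS, Session

SESSION_COLUMNS = ["subject_id", "group", "block", "trial", "action", "reward"]


def write_sessions(cohort: list[Session], path) -> None:
    frames = []
    for sess in cohort:
        frames.append(pd.DataFrame({
            "subject_id": sess.subject_id,
            "group": sess.group,
            "block": sess.blocks,
            "trial": np.arange(sess.n_trials),
            "action": [ACTION_LABELS[a] for a in sess.actions],
            "reward": sess.rewards,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sessions(path) -> list[Session]:
    df = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    bad = ~df["action"].isin(ACTION_LABELS)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise ValueError(f"unknown action symbol at line {line}")
    bad = ~df["reward"].isin((0, 1))
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ValueError(f"reward outside {{0,1}} at line {line}")

    sessions = []
    for sid, g in df.groupby("subject_id", sort=False):
        g = g.sort_values("trial")
        blocks = g["block"].to_numpy()
        if np.any(np.diff(blocks) < 0):
            row = g.index[np.flatnonzero(np.diff(blocks) < 0)[0] + 1]
            raise ValueError(f"blocks out of order at line {int(row) + 2}")
        sessions.append(Session(
            subject_id=str(sid),
            group=str(g["group"].iloc[0]),
            blocks=blocks,
            actions=np.array([ACTION_LABELS.index(a) for a in g["action"]]),
            rewards=g["reward"].to_numpy(),
        ))
    return sessions


def write_trace(trace: np.ndarray, path, actions=None, rewards=None) -> None:
    """Policy trace as delimited text: trial, p_L, p_R[, fed_action, fed_reward]."""
    df = pd.DataFrame({
        "trial": np.arange(len(trace)),
        "p_L": trace[:, 0],
        "p_R": trace[:, 1],
    })
    if actions is not None:
        df["fed_action"] = [ACTION_LABELS[a] for a in actions]
    if rewards is not None:
        df["fed_reward"] = rewards
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
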