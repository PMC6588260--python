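"""Prediction metrics, leave-one-out cross-validation, hyperparameter
selection and diagnostic-label classification.

The two accuracy measures are the per-trial mean negative log-probability
assigned to the actions a subject actually took,

    nlp = -sum_s sum_t log pi_t(a_t^s) / sum_s T_s

(lower is better; ln 2 for a coin-flip model), and the percentage of
trials on which the most probable predicted action matches the taken one
(exact ties count as incorrect).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import (
    PROB_FLOOR,
    FitConfig,
    FittedModel,
    fit_ml,
    session_policies,
)
from .task import Session

GROUP_ORDER = ("healthy", "depression", "bipolar")


def policy_trace(family: str, params, session: Session,
                 reset_per_block: bool = True) -> np.ndarray:
    """Causal per-trial action probabilities (T, 2) of a model."""
    return session_policies(family, params, session, reset_per_block)


def _check_aligned(trace: np.ndarray, session: Session) -> None:
    if trace.shape != (session.n_trials, 2):
        raise ValueError(
            f"trace shape {trace.shape} does not match session with "
            f"{session.n_trials} trials"
        )


def nlp(trace: np.ndarray, session: Session) -> float:
    """Per-trial mean negative log-probability of the taken actions."""
    _check_aligned(trace, session)
    taken = trace[np.arange(session.n_trials), session.actions]
    return float(-np.log(np.clip(taken, PROB_FLOOR, None)).mean())


def cohort_nlp(traces: list[np.ndarray], sessions: list[Session]) -> float:
    """nlp pooled over subjects: total -log prob / total trial count."""
    total, n = 0.0, 0
    for trace, sess in zip(traces, sessions, strict=True):
        _check_aligned(trace, sess)
        taken = trace[np.arange(sess.n_trials), sess.actions]
        total -= float(np.log(np.clip(taken, PROB_FLOOR, None)).sum())
        n += sess.n_trials
    return total / n


def percent_correct(trace: np.ndarray, session: Session) -> float:
    """Percentage of trials whose strictly most probable action was taken."""
    _check_aligned(trace, session)
    taken = trace[np.arange(session.n_trials), session.actions]
    other = trace[np.arange(session.n_trials), 1 - session.actions]
    return float((taken > other).mean() * 100.0)


@dataclass
class CVResult:
    """Per-fold held-out prediction accuracy of one model family."""

    family: str
    folds: pd.DataFrame  # columns: subject_id, nlp, percent_correct
    checkpoint_nlp: pd.DataFrame | None = None  # columns: subject_id, iteration, nlp

    @property
    def mean_nlp(self) -> float:
        return float(self.folds["nlp"].mean())

    @property
    def mean_percent_correct(self) -> float:
        return float(self.folds["percent_correct"].mean())

    def save(self, path) -> None:
        self.folds.to_csv(path, index=False)


def loo_cv(family: str, cohort: list[Session], config: FitConfig | None = None,
           *, eval_checkpoints: bool = False, **hyper) -> CVResult:
    """Leave-one-out cross-validation: one fold per subject.

    Each fold fits the family to all other subjects and evaluates nlp and
    %correct on the withheld subject with frozen parameters.  With
    ``eval_checkpoints`` the held-out nlp is also recorded at every stored
    optimisation checkpoint (the early-stopping grid).
    """
    if len(cohort) < 2:
        raise ValueError("leave-one-out needs at least two subjects")
    config = config or FitConfig()
    rows = []
    ckpt_rows = []
    for i, held in enumerate(cohort):
        train = cohort[:i] + cohort[i + 1:]
        try:
            model = fit_ml(family, train, config, **hyper)
        except FloatingPointError as err:  # fold failure is recorded, not fatal
            rows.append({"subject_id": held.subject_id, "nlp": np.nan,
                         "percent_correct": np.nan, "error": str(err)})
            continue
        trace = model.policy_trace(held)
        rows.append({
            "subject_id": held.subject_id,
            "nlp": nlp(trace, held),
            "percent_correct": percent_correct(trace, held),
        })
        if eval_checkpoints:
            for it, params in model.checkpoints.items():
                tr = session_policies(family, params, held,
                                      config.reset_per_block)
                ckpt_rows.append({"subject_id": held.subject_id,
                                  "iteration": it, "nlp": nlp(tr, held)})
    return CVResult(
        family=family,
        folds=pd.DataFrame(rows),
        checkpoint_nlp=pd.DataFrame(ckpt_rows) if eval_checkpoints else None,
    )


def select_hyperparams(family: str, cohort: list[Session], grids: dict,
                       mode: str = "in_sample",
                       other_cohorts: list[list[Session]] | None = None,
                       config: FitConfig | None = None) -> tuple[dict, float]:
    """Pick the hyperparameter setting minimising LOO-CV mean nlp.

    ``grids`` maps hyperparameter names to candidate values: ``n_cells``
    (with the iteration grid taken from optimisation checkpoints), ``J``
    for LIN, ``d`` for GQL.  ``mode='other_groups'`` pools the supplied
    other groups' cohorts and selects on them instead of on ``cohort``.
    """
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ValueError("grids must be non-empty")
    if mode == "other_groups":
        if not other_cohorts:
            raise ValueError("mode='other_groups' requires other_cohorts")
        selection_cohort = [s for c in other_cohorts for s in c]
    elif mode == "in_sample":
        selection_cohort = cohort
    else:
        raise ValueError(f"unknown mode {mode!r}")
    config = config or FitConfig()

    best: tuple[dict, float] | None = None
    if family == "rnn":
        for n_cells in grids.get("n_cells", [10]):
            res = loo_cv("rnn", selection_cohort, config,
                         eval_checkpoints=True, n_cells=n_cells)
            table = res.checkpoint_nlp.groupby("iteration")["nlp"].mean()
            # final iterate is also a candidate
            table.loc[config.max_iterations] = res.mean_nlp
            it = int(table.idxmin())
            score = float(table.min())
            if best is None or score < best[1]:
                best = ({"n_cells": n_cells, "iterations": it}, score)
    else:
        key = {"lin": "J", "gql": "d"}.get(family)
        values = grids.get(key, [None]) if key else [None]
        for v in values:
            hyper = {key: v} if key and v is not None else {}
            res = loo_cv(family, selection_cohort, config, **hyper)
            score = res.mean_nlp
            if best is None or score < best[1]:
                best = (hyper, score)
    return best


def classify_subject(session: Session, group_models: dict[str, FittedModel],
                     label_order: tuple[str, ...] | None = None) -> str:
    """Label of the group model with the lowest nlp on the session.

    Ties are broken deterministically by ``label_order`` (defaults to the
    order of ``group_models``).
    """
    if len(group_models) < 2:
        raise ValueError("need at least two group models")
    order = label_order or tuple(group_models)
    scores = {
        label: nlp(group_models[label].policy_trace(session), session)
        for label in order
    }
    return min(order, key=lambda lab: (scores[lab], order.index(lab)))


@dataclass
class ConfusionMatrix:
    """True-label by predicted-label subject counts."""

    labels: tuple[str, ...]
    counts: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = np.zeros((len(self.labels), len(self.labels)), dtype=int)

    def add(self, true_label: str, predicted_label: str) -> None:
        self.counts[self.labels.index(true_label),
                    self.labels.index(predicted_label)] += 1

    @property
    def row_percent(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, 100.0 * self.counts / totals, 0.0)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        pct = self.row_percent
        data = {
            pred: [f"{self.counts[i, j]} ({pct[i, j]:.0f}%)"
                   for i in range(len(self.labels))]
            for j, pred in enumerate(self.labels)
        }
        return pd.DataFrame(data, index=list(self.labels))

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index_label="true_label")


def classify_cohorts(cohorts: dict[str, list[Session]], family: str = "rnn",
                     config: FitConfig | None = None,
                     refit_without_subject: bool = True,
                     **hyper) -> ConfusionMatrix:
    """Leave-one-out diagnostic-label prediction across groups.

    For each subject the model of their own group is refitted without them
    (the other groups' models are fitted once on all their subjects); the
    predicted label is the group whose model gives the lowest nlp.
    """
    config = config or FitConfig()
    labels = tuple(cohorts)
    full_models = {
        g: fit_ml(family, sessions, config, **hyper)
        for g, sessions in cohorts.items()
    }
    cm = ConfusionMatrix(labels)
    for g, sessions in cohorts.items():
        for i, held in enumerate(sessions):
            models = dict(full_models)
            if refit_without_subject and len(sessions) > 1:
                rest = sessions[:i] + sessions[i + 1:]
                models[g] = fit_ml(family, rest, config, **hyper)
            cm.add(g, classify_subject(held, models, label_order=labels))
    return cm
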