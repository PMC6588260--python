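"""Synthetic labelled cohorts.

Generates on-policy sessions from parameterised agents so that every
pipeline stage (fitting, cross-validation, simulation, statistics,
classification) is testable without clinical data.  Three built-in
GQL-based phenotypes emulate the qualitative group signatures seen in
this task family:

* ``healthy``  — reward-maximising with a post-reward switch 'dip'
  (negative fast-value weight), dip magnitude shrinking with accumulated
  rewards (positive slow-value weight), and perseveration that decays the
  longer a run lasts;
* ``depression`` — weaker value control and an elevated fraction of
  length-1 runs;
* ``bipolar`` — an alternation tendency such that one switch raises the
  probability of further switching (symmetric length-1 oscillations),
  with long runs stabilised by a slow history trace.

Preset numbers are implementation choices verified by
:func:`verify_phenotype`; they are not estimates from any dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agents import GQLParams
from .fitting import inverse_transform, make_agent, transform_params
from .simulate import run_on_policy
from .stats import (
    fraction_length1_runs,
    p_best_action,
    stay_by_rewards_since_switch,
    stay_prob_given_reward,
)
from .task import DEFAULT_TRIALS_PER_BLOCK, Session, build_schedule


@dataclass(frozen=True)
class PhenotypeSpec:
    """Recipe for one synthetic group."""

    label: str
    family: str
    params: object
    n_subjects: int = 34
    trials_per_block: int = DEFAULT_TRIALS_PER_BLOCK
    jitter: float = 0.1  # multiplicative spread on the unconstrained scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


def _jittered_params(spec: PhenotypeSpec, rng, d: int | None) -> object:
    """Per-subject parameters: multiplicative jitter on the unconstrained
    scale, resampled (and logged via count) if any rate leaves [0, 1]."""
    u = inverse_transform(spec.params)
    kwargs = {"d": d} if d is not None else {}
    for _ in range(100):
        u_j = u * (1.0 + spec.jitter * rng.standard_normal(u.shape))
        try:
            return transform_params(spec.family, u_j, **kwargs)
        except ValueError:
            continue
    raise RuntimeError("could not draw valid jittered parameters")


def generate_cohort(spec: PhenotypeSpec, schedule_seed: int = 0,
                    schedule_kwargs: dict | None = None) -> list[Session]:
    """On-policy sessions from jittered agents on independently shuffled
    schedules; fully determined by the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    d = spec.params.d if isinstance(spec.params, GQLParams) else None
    kwargs = dict(schedule_kwargs or {})
    kwargs.setdefault("trials_per_block", spec.trials_per_block)
    sessions = []
    for i in range(spec.n_subjects):
        params = (_jittered_params(spec, rng, d) if spec.jitter > 0
                  else spec.params)
        schedule = build_schedule(seed=schedule_seed * 10_000 + i, **kwargs)
        agent = make_agent(spec.family, params)
        sess = run_on_policy(
            agent, schedule, seed=int(rng.integers(2**31)),
            subject_id=f"{spec.label}-{i:03d}", group=spec.label,
        )
        sessions.append(sess)
    return sessions


def phenotype_presets(n_subjects: int = 34,
                      trials_per_block: int = DEFAULT_TRIALS_PER_BLOCK,
                      jitter: float = 0.1) -> dict[str, PhenotypeSpec]:
    """Built-in GQL (d=2) phenotypes; component order is (fast, slow)."""
    healthy = GQLParams(
        Phi=np.array([0.50, 0.06]),
        Psi=np.array([0.70, 0.04]),
        B=np.array([-4.0, 12.0]),
        K=np.array([3.0, -2.5]),
        C=np.zeros((2, 2)),
    )
    depression = GQLParams(
        Phi=np.array([0.50, 0.06]),
        Psi=np.array([0.55, 0.04]),
        B=np.array([-2.5, 7.0]),
        K=np.array([1.2, -1.5]),
        C=np.zeros((2, 2)),
    )
    bipolar = GQLParams(
        Phi=np.array([0.50, 0.06]),
        Psi=np.array([0.85, 0.06]),
        B=np.array([-1.5, 6.0]),
        K=np.array([-0.5, 1.3]),
        C=np.zeros((2, 2)),
    )
    return {
        label: PhenotypeSpec(label=label, family="gql", params=p,
                             n_subjects=n_subjects,
                             trials_per_block=trials_per_block,
                             jitter=jitter, seed=100 + i)
        for i, (label, p) in enumerate(
            [("healthy", healthy), ("depression", depression),
             ("bipolar", bipolar)]
        )
    }


def verify_phenotype(cohort: list[Session],
                     expectations: dict | None = None) -> dict:
    """Check a cohort against qualitative phenotype signatures.

    Default expectations: above-chance reward seeking and a negative
    immediate reward effect on staying.  Optional keys: ``monotone_bins``
    (stay-after-reward increases from the 0-rewards to the >2-rewards
    bin), ``min_length1`` / ``max_length1`` bounds on the fraction of
    length-1 runs.  Tolerances scale with cohort size as binomial
    standard errors.
    """
    expectations = {"p_best_above_chance": True, "reward_dip": True,
                    **(expectations or {})}
    n_trials = sum(s.n_trials for s in cohort)
    se = 1.5 / np.sqrt(n_trials)  # pooled binomial scale
    p_best = float(np.mean([p_best_action(s) for s in cohort]))
    stay = np.array([stay_prob_given_reward(s) for s in cohort])
    p_stay_r, p_stay_nr = np.nanmean(stay, axis=0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # sparse bins -> nan
        bins = np.nanmean(
            [stay_by_rewards_since_switch(s) for s in cohort], axis=0
        )
    frac1 = float(np.mean([fraction_length1_runs(s) for s in cohort]))

    report = {
        "p_best": p_best,
        "p_stay_reward": float(p_stay_r),
        "p_stay_no_reward": float(p_stay_nr),
        "stay_by_reward_bins": bins.tolist(),
        "fraction_length1_runs": frac1,
        "checks": {},
    }
    checks = report["checks"]
    if expectations.get("p_best_above_chance"):
        checks["p_best_above_chance"] = bool(p_best > 0.5 + se)
    if expectations.get("reward_dip"):
        checks["reward_dip"] = bool(p_stay_r < p_stay_nr - se)
    if expectations.get("monotone_bins"):
        checks["monotone_bins"] = bool(bins[3] > bins[0])
    if "min_length1" in expectations:
        checks["min_length1"] = bool(frac1 >= expectations["min_length1"])
    if "max_length1" in expectations:
        checks["max_length1"] = bool(frac1 <= expectations["max_length1"])
    report["passed"] = all(checks.values())
    return report
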