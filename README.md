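# banditfit

Tools for modelling human trial-by-trial decision-making in two-armed
bandit tasks: classical reinforcement-learning baselines, a generalised
Q-learning model, a lagged logistic regression, and an LSTM network
trained to imitate choice sequences — together with the maximum-likelihood
fitting, leave-one-out cross-validation, on-/off-policy simulation,
behavioural statistics and diagnostic-label classification used to
compare and interpret them.

The intended users are computational-psychiatry and cognitive-modelling
researchers who want to (a) fit interpretable choice models to bandit
data, (b) benchmark them against a flexible recurrent-network imitator
that makes minimal structural assumptions, and (c) interrogate any fitted
model with controlled forced-input probes.

## Models

All models predict the probability of pressing L or R on the next trial
from the trial history, strictly causally, behind one agent contract
(`reset` / `predict` / `observe`):

| family | policy logit (L vs R) | free parameters |
|--------|----------------------|-----------------|
| `ql`   | β (Q(L) − Q(R)), delta-rule values | φ, β (2) |
| `qlp`  | ql + κ for repeating the last action | φ, β, κ (3) |
| `gql`  | B·Q(a) + K·H(a) + H(a)ᵀC Q(a), d value and d history traces per action | 4d + d² (5 / 12 / 140 at d = 1 / 2 / 10) |
| `lin`  | μ₀ + Σⱼ μⱼ a_{t−j} + γⱼ r_{t−j} + ζⱼ a_{t−j} r_{t−j} | 1 + 3J |
| `rnn`  | softmax(Vᵀh_t), single LSTM layer | 4(N_c(N_a+1) + N_c² + N_c) + N_c N_a (190 / 580 / 1960 at 5 / 10 / 20 cells) |

Fitting maximises the summed log-probability of the taken actions over a
cohort, with analytic gradients throughout (forward-mode sensitivities
for the Q-learning family, backpropagation through time for the LSTM —
both implemented in numpy and checked against finite differences).
Prediction quality is measured by `nlp`, the per-trial mean negative
log-probability assigned to the actions a subject actually took, and by
the percentage of actions predicted correctly. See `docs/methods.md`
for the full model and estimation details.

Because clinical data are not distributable, the package includes a
synthetic-cohort module with three GQL-based phenotypes (healthy-like,
depression-like, bipolar-like) that carry the qualitative signatures the
analyses probe: above-chance reward seeking, a post-reward switch "dip",
perseveration that decays over a run, and symmetric length-1
oscillations.

## Worked example

```python
from banditfit import (FitConfig, fit_ml, generate_cohort, loo_cv,
                       phenotype_presets, verify_phenotype)

presets = phenotype_presets(n_subjects=8, trials_per_block=60)
cohort = generate_cohort(presets["healthy"])

report = verify_phenotype(cohort)
print(f"p(best action)      = {report['p_best']:.3f}")
print(f"p(stay | reward)    = {report['p_stay_reward']:.3f}")
print(f"p(stay | no reward) = {report['p_stay_no_reward']:.3f}")

for family in ("ql", "gql"):
    cv = loo_cv(family, cohort, FitConfig(seed=0, n_restarts=2), d=2)
    print(f"{family:>4}: held-out nlp = {cv.mean_nlp:.3f}, "
          f"%correct = {cv.mean_percent_correct:.1f}")
```

prints

```
p(best action)      = 0.540
p(stay | reward)    = 0.839
p(stay | no reward) = 0.922
  ql: held-out nlp = 0.672, %correct = 48.4
 gql: held-out nlp = 0.280, %correct = 89.9
```

The synthetic healthy-like cohort seeks reward above chance (0.540 >
0.5) yet is *less* likely to stay after a reward than after none
(0.839 < 0.922) — the post-reward "dip". Plain Q-learning cannot
represent that direction of reward effect, so its held-out nlp (0.672)
is close to the coin-flip bound ln 2 ≈ 0.693, while generalised
Q-learning, whose value weights may be negative, predicts the held-out
subjects well (0.280).

A command-line interface covers the same pipeline end to end:

```
banditfit simulate --preset bipolar --n-subjects 34 --out cohort.csv
banditfit crossval --family rnn --cells 5,10,20 --sessions cohort.csv --out cv.csv
banditfit offpolicy --family gql --sessions cohort.csv --probe oscillation --out trace.csv
banditfit classify --family gql --sessions all_groups.csv --out confusion.csv
```

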