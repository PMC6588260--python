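# Methods

## The task

A two-armed bandit with actions L and R. The task is divided into blocks
with fixed Bernoulli reward probabilities; one action is always better.
The default schedule has 12 blocks: better-action probabilities
{0.25, 0.125, 0.08} against a 0.05 baseline, each (probability, side)
pair appearing twice, block order shuffled under a seed. Trials are
self-paced in the real task; the package models the resulting data shape
with a per-block trial count (default 110, matching typical per-block
averages of roughly 103–115 trials), either fixed or drawn from a seeded
sampler — response timing itself is not modelled. Rewards are coded
binary; distinct reward identities (different snack types in the original
task) carry no information for any model here and are collapsed.

## Model families

All families implement the same strictly causal contract: `reset()`,
`predict()` (the policy for the upcoming trial, computed before its
action is seen), `observe(action, reward)`. State is cleared at block
boundaries by default (`reset_per_block`), reflecting the fact that
blocks are separated by rating screens; the flag is exposed because the
right convention for baseline models is not observable from the data
shape alone.

**QL.** One value per action, delta rule
`Q(a) <- (1-phi) Q(a) + phi r` for the taken action, softmax policy with
inverse temperature `beta > 0`. Free parameters: `phi in [0,1]`, `beta`.

**QLP.** QL plus a perseveration bonus `kappa` added to the logit of the
previously taken action (zero on the first trial after a reset).
`kappa = 0` recovers QL exactly.

**GQL.** Depth-`d` generalisation: each action carries a vector of `d`
values updated elementwise with rates `Phi`, and a vector of `d`
action-history traces updated with rates `Psi` (the taken action's
traces move toward 1, all others decay toward 0 — a convex update, so
histories stay in [0,1]). The policy logit is
`B.Q(a) + K.H(a) + H(a)' C Q(a)` with free weight vectors `B`, `K` and
interaction matrix `C`, giving `4d + d^2` parameters (5, 12, 140 at
d = 1, 2, 10). With `d = 1, Psi = [1], C = 0` the history trace becomes
the last-action indicator and GQL reproduces QLP trial by trial. A
negative entry of `B` makes higher values *reduce* the probability of
staying — the mechanism behind the post-reward switch "dip" that plain
QL cannot express.

**LIN.** Logistic regression of the L/R log-odds on the previous `J`
trials' actions, rewards and their interactions (1 + 3J parameters;
default J = 18, selectable by cross-validation). Coding convention:
actions enter as +1 (L) / -1 (R) so that zero-padding before the window
is neutral and the intercept is a pure side bias; rewards enter as 0/1.
The fit is invariant to the coding up to sign flips of the
action-dependent weights (tested). Lags do not cross block boundaries
under the default reset convention.

**RNN.** A single LSTM layer (standard gates, no peepholes, no
forget-gate bias offset) feeding a bias-free softmax readout. Inputs are
the one-hot previous action plus the previous binary reward (dimension
N_a + 1); the first trial after a reset feeds the zero vector from zero
cell states. Parameter count is
`4 (N_c (N_a+1) + N_c^2 + N_c) + N_c N_a` — 190, 580, 1960 at 5, 10, 20
cells with two actions.

## Estimation

A single model per cohort (group) is fitted by maximum likelihood: the
objective is the summed negative log-probability of every subject's
taken actions. Constrained parameters are optimised in an unconstrained
space (learning rates through the logistic function, `beta` through the
exponential; weights untransformed). Probabilities are floored at 1e-12
before taking logs.

Gradients are analytic throughout, implemented in numpy and verified
against central finite differences in the test suite:

* QL/QLP/GQL use forward-mode sensitivities — each value trace depends on
  a single learning rate, so one state-shaped array per rate block
  carries all derivatives;
* the LSTM uses backpropagation through time, with gradient flow cut at
  reset boundaries.

The LSTM is trained with full-batch Adam (default step size 0.01; the
scaled test fixtures use 0.02) from one fixed seeded uniform(-0.1, 0.1)
initialisation per network size, reused across fits, so that repeated
fits of the same architecture are directly comparable. Parameter
snapshots are stored every `checkpoint_every` iterations; this grid is
what early stopping selects over. The Q-learning family defaults to
L-BFGS with the same analytic gradients — at 2–12 parameters
quasi-Newton convergence takes a few dozen evaluations where Adam needs
thousands — with seeded random restarts (default 5) against local
optima; Adam remains available for every family. LIN is fitted as a
standard binomial logistic regression on its lagged design matrix
(scikit-learn, unpenalised); perfect separation is capped by the
optimiser's iteration limit rather than diverging. One iteration means
one full-cohort gradient step.

## Evaluation

`nlp` is the per-trial mean negative log-probability (the cohort NLL
divided by the total trial count); `%correct` scores the strictly most
probable action against the taken one, with exact ties counted as
incorrect (so a coin-flip model scores 0, not 50). Leave-one-out
cross-validation fits on all subjects but one and evaluates the held-out
subject with frozen parameters; hyperparameters (cells and iteration
count for the RNN, `J` for LIN, `d` for GQL) are chosen to minimise the
CV mean nlp, either in-sample or — to avoid using a group's own data —
on the pooled other groups. Diagnostic labels are predicted by refitting
the held-out subject's group model without them and assigning the label
of the group model with the lowest nlp; ties break by a fixed label
order.

## Simulation

*Off-policy*: a forced (action, reward) sequence is fed to a frozen
agent and only its predictions are recorded; the trace depends only on
the inputs and parameters, never on the agent's own outputs.
*On-policy*: the agent samples (or greedily takes) its own actions and
receives schedule feedback. *Mixed*: a forced prefix followed by a
greedy continuation with zero continuation rewards by default — greedy
so that probe outcomes are deterministic, zero-reward so the
continuation isolates action-history dynamics. The packaged probes are a
30-trial reward-switch design (10 forced R then 20 forced L, rewards at
configurable positions — the shipped placements are illustrative
defaults) and a 20-trial oscillation probe (forced
R,R,R,R,R,R,L,R,L then 11 greedy trials).

## Behavioural statistics

Stay probabilities conditioned on the previous reward, stay probability
binned by rewards earned since switching (bins 0/1/2/>2; the count
excludes the current trial's reward), stay probability by repeats since
switching restricted to trials with no reward on the trial and none
since the switch, run-length decompositions, and the median current-run
length per previous-run length (median, not mean, to expose the modal
run length). All pairwise statistics stay within blocks.

## Synthetic cohorts

Three GQL (d = 2) phenotypes stand in for the clinical groups so the
full pipeline is testable without patient data. All share a fast value
trace (rate 0.5) with a negative weight — producing the post-reward
dip — and a slow value trace (rate 0.06) with a positive weight that
accumulates within a block and directs choice toward the better action,
shrinking the dip as rewards accrue:

* **healthy**: B = (-4, 12), history rates (0.7, 0.04) with
  K = (3, -2.5) — strong fast perseveration that decays as the slow
  history trace grows; ~19% of runs have length 1;
* **depression**: weaker policy weights, B = (-2.5, 7), K = (1.2, -1.5),
  history rates (0.55, 0.04); noisier choice, ~42% length-1 runs;
* **bipolar**: B = (-1.5, 6), history rates (0.85, 0.06) with
  K = (-0.5, 1.3) — a fast alternation drive stabilised by a slow
  perseverative trace, so one switch raises the probability of further
  switching while long runs remain locally stable; length-1 runs
  dominate (~58%).

Between-subject heterogeneity is emulated by ±10% multiplicative jitter
on the unconstrained parameter scale (resampled if a rate leaves its
support). The preset numbers were chosen once by simulating candidate
settings against the qualitative signatures and are verified by
`verify_phenotype`; they are design choices, not estimates of any
dataset. What the generator does **not** emulate: reaction times,
within-session drift (fatigue, medication), reward-identity effects, and
the long-range oscillation matching seen in real patient data — GQL
generators cannot produce run-length matching beyond length 1, which is
precisely the regime where only the LSTM succeeds. Tests passing on
these cohorts therefore show that the pipeline recovers structure a
generator of this class puts in, not that the presets are faithful
patient models.

## Numerical choices and scaled test sizes

Softmax and log-sigmoid computations are max-subtracted / `logaddexp`
stabilised; rates are clipped to [1e-16, 1-1e-16] so extreme
unconstrained values never underflow to exactly 0 or 1; argmax ties in
greedy action selection resolve to L (index order) and are therefore
deterministic. The test suite runs its heavy end-to-end checks at scaled
sizes chosen as the smallest that leave the qualitative outcomes stable:
training cohorts of 15 subjects x 12 blocks x 80 trials, 5-cell
networks, 500 Adam iterations; parameter-recovery checks keep the full
34-subject x 12 x 110 design.

## Known limitations

Single-level (non-hierarchical) fitting only; no Bayesian model
evidence or information criteria; two actions are assumed throughout the
analytic gradient implementations; LSTM training is CPU numpy
(full-batch, no minibatching), adequate for cohort-scale behavioural
data but not for much larger corpora; probe reward placements in the
reward-switch design are configurable defaults rather than canonical
values.
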