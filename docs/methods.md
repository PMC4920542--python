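# Methods

## The task

`rlcontext` models behaviour in a probabilistic instrumental learning
task with a 2x2 factorial design crossing outcome valence with feedback
information. Four fixed cue pairs (choice contexts) are each presented
20 times (80 learning trials), interleaved pseudo-randomly. Within a
pair, the "correct" cue delivers the good outcome with probability 0.75
and the "incorrect" cue with probability 0.25, the two cues' outcomes
being sampled independently (so under Complete feedback both cues show
the same outcome on 37.5% of trials: `0.75*0.25 + 0.25*0.75`). Good/bad
outcomes are +1/0 points in Reward contexts and 0/-1 in Punishment
contexts. In Partial-feedback contexts only the chosen cue's outcome is
shown; in Complete-feedback contexts the unchosen cue's (counterfactual)
outcome is shown as well. After learning, a transfer test presents all
28 pairings of the 8 cues, 4 times each (112 trials), without feedback.

The synthetic generator (`rlcontext.task`) reproduces this structure:

- **Pseudo-randomisation** is blocked: every consecutive block of 4
  trials contains one trial per context, with block-internal order
  shuffled. This keeps contexts interleaved, which is the common
  practice in this task family; the alternative (full-session shuffle)
  changes nothing the models are sensitive to, since learning state is
  per-context.
- **Side counterbalancing** is exact: the correct cue appears on each
  side exactly 10 times per context, which requires an even trial count
  per context (odd counts raise an error).
- **Outcomes** are fresh independent Bernoulli draws per trial, not a
  pre-shuffled fixed 15/5 sequence; the schedules are stated as
  probabilities, and live sampling is the matching generative
  assumption.
- **Reaction times are not generated**: no model in the lattice
  produces latencies. The RT smoothing statistic can be exercised on
  any user-supplied series.
- Every simulated trial contains a choice; response omissions are not
  modelled.

What the generator does *not* emulate about real data: subject-level
heterogeneity of parameters within a cohort (each simulated group is
parameter-homogeneous unless the caller varies parameters), sequential
effects such as fatigue or drifting attention, response-time coupling
with values, and missed trials. Tests passing on this generator
therefore validate the estimation and selection machinery under the
stated generative assumptions, not robustness to those real-data
features.

## The model lattice

All models are delta-rule learners over per-context option values
Q(s, .) with softmax choice
P(a) = 1 / (1 + exp(beta * (Q(s,b) - Q(s,a)))).

- **M1 (factual)**: Q(s,c) += alpha1 * (R_c - Q(s,c)).
- **M2 (+ counterfactual)**: under Complete feedback additionally
  Q(s,u) += alpha2 * (R_u - Q(s,u)); under Partial feedback the
  counterfactual prediction error is defined as zero.
- **M3 (+ contextual)**: a context value V(s) tracks the average trial
  outcome, V(s) += alpha3 * (R_tot - V(s)) with
  R_tot = (R_c + R_u)/2 (Complete) or (R_c + Q_t(s,u))/2 (Partial),
  and V(s) re-references both option prediction errors:
  delta_C = R_c - V(s) - Q(s,c), delta_U = R_u - V(s) - Q(s,u).
  Option values thereby become relative to their context, which is what
  lets the model learn punishment avoidance as well as reward seeking
  (a frequent neutral outcome in a punishing context carries a positive
  relative value).
- **M4**: contextualisation without the counterfactual module
  (alpha2 = 0), the control model of the supplementary comparison.

Numerical conventions:

- **Initialisation** Q = V = 0: the symmetric prior between +1 and -1
  outcomes; it yields the first-trial choice probability of 0.5 that
  the ex-post analyses assume.
- **Update order**: all prediction errors are computed from the trial's
  pre-update Q and V, then the three updates are applied
  simultaneously; the Partial-feedback R_tot uses the pre-update
  Q_t(s,u). (Whether delta_V should instead see the just-updated
  unchosen value is undeterminable from the equations' subscripts; the
  pre-update convention is used throughout and the step API makes the
  state explicit, so the alternative is a three-line variant for anyone
  who needs it.)
- **Softmax** is evaluated through `logaddexp`, so log-likelihoods are
  finite for any finite beta.
- Nesting is exact by construction: running M3 with alpha3 = 0 (or
  alpha2 = alpha3 = 0) is bit-identical to M2 (M1), which the suite
  asserts trial-by-trial.
- The replay/likelihood hot loops are jit-compiled (numba) duplicates
  of the step API; their numerical equivalence is asserted in tests.

## Fitting

Subject-level fits use multi-start bounded optimisation (L-BFGS-B, 20
restarts by default, starting points drawn from the priors,
deterministic given the seed). Bounds: 0 < beta < 100 (the numerical
stand-in for an unbounded inverse temperature; fits at the bound are
flagged) and 0 <= alpha <= 1, with each model's pinned rates held at
exactly 0. Fits report how many restarts reached within 1e-3 nats of
the best optimum; on simulated data at the study scale this is
typically 18-20 of 20, i.e. the likelihood surface is benign. For
nested-model chains, callers can pass the embedded optimum of the
simpler model as an extra starting point (`extra_starts`), which makes
the NLL monotonicity of nested fits hold exactly at the optimum.

MAP fits maximise log-likelihood plus log-prior. Priors (identical for
all subjects and groups, so selection is not biased by them):
Gamma(shape 1.2, scale 5) on beta — weakly informative, mode ~1,
mean 6 — and Beta(1.1, 1.1) on each learning rate — near-flat with a
gentle repulsion from the bounds that keeps the MAP interior. The
"minimised LPP" of the literature is implemented as maximisation of the
log posterior; `FitResult.lpp` stores the log posterior at the MAP.

**Laplace evidence.** The log marginal likelihood is approximated as
log P(D|th) + log P(th) + (k/2) log 2pi - (1/2) log det H, with H the
finite-difference Hessian (central differences, step 1e-4) of the
negative log posterior at the mode. The integral is evaluated in
log(beta)/logit(alpha) coordinates with the Jacobian folded into the
density: the marginal likelihood is parameterisation-free, but the
Gaussian approximation is not, and when a learning rate's posterior is
squeezed against a bound the natural-scale Laplace underestimates the
evidence of the fuller models. The chart's mode is located by a short
local optimisation started from the natural-coordinate MAP. The
reported parameter estimates remain the natural-coordinate MAP (so a
flat prior reproduces the MLE argmax exactly). If the Hessian is not
positive definite the evidence falls back to a BIC-style penalty,
-NLL - (k/2) log n, with a logged warning. The generic Laplace utility
is exact for Gaussian log-posteriors and agrees with the Beta-Bernoulli
conjugate closed form within 0.01 nats at n = 80.

Group-level fits estimate one parameter vector per cohort by summing
the per-subject objective (either summed NLL or summed log-likelihood
plus a single log-prior; both objectives are provided because the
group-level convention is not fixed).

## Model selection

`rfx_bms` implements the standard variational random-effects scheme:
subject model labels are multinomial draws from Dirichlet-distributed
population frequencies (uniform prior, alpha0 = 1 per model); the
variational iteration alternates subject responsibilities
u_nk ∝ exp(ev_nk + psi(alpha_k) - psi(sum alpha)) with the concentration
update alpha = alpha0 + sum_n u_n, to convergence (max |d alpha| <
1e-6, cap 500 iterations). Expected frequency (PP) is alpha/sum(alpha);
exceedance probability (XP) is estimated from 1e6 Monte-Carlo Dirichlet
draws with a fixed seed (argmax ties have measure zero for continuous
draws). PP and XP each sum to one and are invariant to per-subject
additive shifts of the evidence row.

On tiny cohorts the variational posterior is more concentrated than
the exact Dirichlet-multinomial enumeration: expected frequencies agree
to <0.05 on a 3-subject toy, while the variational XP overshoots the
exact one by ~0.1 — an inherent property of the approximation (shared
by the standard toolboxes), asserted as such in the tests.

Fixed-effects comparison (softmax of summed evidences), BIC
(2*NLL + k log n) and pairwise 2*delta-logL tables (including a chance
baseline at n*ln 2) are provided alongside.

## Simulation and behavioural measures

Ex-ante cohorts (default N = 1000, beta = 5.0, all alphas 0.3) report
mean final option values, decision values Q(correct) - Q(incorrect),
trial-by-trial correct-choice probability, and post-learning softmax
choice rates. These reproduce the lattice's signatures: M1 shows a
reward/punishment asymmetry and no feedback effect; M2 adds a
punishment-complete improvement; M3 equalises valences and benefits
from complete feedback, and inverts preferences between the
intermediate cues in the transfer test (the frequently-neutral
punishment cue L25 beats the rarely-winning reward cue G25 once values
are contextualised). "Similar performance" is operationalised as a mean
correct-choice probability gap below 0.05 at N = 1000 — an order of
magnitude below M1's valence gap at these parameters (~0.075), and a
comfortable margin above the observed "similar" gaps (< 0.01). The
ex-ante battery is a property suite, not inference: the cohort size is
arbitrary, so no statistical tests are attached.

Ex-post simulation replays a subject's actual choices and outcomes and
returns the model's per-trial probability of the correct choice (0.5 at
trial 1 by construction); the probability sequence itself is the
primary output, with an optional resampling mode for generative checks.
Post-learning choices are simulated as softmax over final learning-task
Q-values with the learning-task beta; a transfer-specific beta refit is
available but is not part of any validation.

Behavioural measures: trial-by-trial cumulative correct-choice average
per context (with improvement = trial 20 minus trial 1, chance 0, and
final rate, chance 0.5); reaction-time series smoothed with a centred
three-trial window, truncated to the two available trials at both
edges (the series ends are therefore two-point means — flagged here
because the smoothing convention at the edges is not standardised);
post-learning per-cue choice rates (chosen/presented) and per-context
cue discrimination (correct minus incorrect cue rate, chance 0).
Cohort-level emitters produce mean +/- s.e.m. tables per group in the
shapes these results are conventionally reported (model comparison per
group x model; choice rate per context with an Overall row; transfer
rate per cue). Group inference (ANOVA, t-tests) is deliberately out of
scope: the package emits tidy dependent-measure tables for standard
statistics tooling.

## Recovery validation

Model recovery simulates two virtual groups (defaults: M1 with 18
subjects and M3 with 20, beta = 5, alphas 0.3 — mirroring the ex-ante
parameter convention and the study's group sizes), fits M1-M3 to every
subject by MAP (8 restarts inside the recovery driver), and runs the
random-effects selection per group with identical priors; it reports
PP/XP per candidate, mean BIC, and whether the generating model won.
Parameter recovery refits simulated cohorts over a grid of generating
values and reports median/IQR per parameter; at the study scale the
recovered alpha1 medians are accurate (0.10/0.27/0.48 for generating
0.1/0.3/0.5) and monotone.

Known limitation: with 80 trials per subject the contextual learning
rate alpha3 is weakly identified per subject (fitted values scatter
across most of [0, 1] for a generating value of 0.3). In roughly 15% of
simulated M3 cohorts of 20 subjects the summed evidence genuinely
favours the counterfactual-only model M2 over M3 — the contextual
module's likelihood gain does not overcome the Occam penalty of the
fourth parameter on that draw. Cohort-level model identification under
these conditions is therefore reliable but not near-certain, and the
replicated-recovery test documents the achieved rate rather than an
idealised one. The basic-vs-full distinction (M1 vs M3) is essentially
never confused.

## Problem sizes used by the test suite

Chosen as the package's own validation design: ex-ante battery at
N = 1000 agents per model; replicated model recovery with 20
two-group replications at the default group sizes; parameter recovery
with 100 subjects per grid point; empirical outcome checks at 1e5
draws; exceedance probabilities from 1e6 Dirichlet draws (1e5 inside
the replicated recovery loop). All randomness is seeded; every
reported number is recomputed at run time.
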