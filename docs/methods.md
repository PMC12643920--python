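# Methods

## Decision model

Each trial offers a baseline option (1 credit, no cost) against a costly
option (reward *R* ∈ {2,4,6,8,10} credits at cost level *C* ∈ 1..5). The
costly option's subjective value is

- linear `SV = R − k·C`
- parabolic `SV = R − k·C²`
- hyperbolic `SV = R / (1 + k·C)`

and `P(costly) = logistic(β·(SV − 1))`. Cost enters the model as the
integer level 1–5 for both tasks by default (`cost_coding="level"`), which
keeps *k* on a common scale across tasks and participants even though the
physical costs (fraction of maximum grip force; seconds of waiting) are
individually calibrated; `cost_coding="physical"` switches to the
`cost_value` column. Linear and parabolic subjective values may be
negative; hyperbolic values lie in (0, R].

*k* and β are each "joint" (one value per subject) or "separate" (one per
recipient: self vs environment), crossing to 12 models. Joint models are
exactly the separate models with tied values, which the tests verify as a
likelihood identity.

Likelihood conventions: omitted trials (no decision within the response
window) carry no choice information and are excluded; chosen-costly trials
on which the effort execution subsequently failed still count as costly
*choices* — the decision, not the execution, is the modelled event.

## Hierarchical estimation

Subject log-parameters are normal at the group level:
`log θ_s = μ + σ·z_s`, `z_s ~ N(0,1)` (non-centered), with weakly
informative hyperpriors `μ ~ N(0,1)` and `σ ~ HalfNormal(0.5)`. These are
the package's own defaults, standard for positivity-constrained
decision-model parameters at this scale of data; they are deliberately
shared with the synthetic-cohort generator's population family so that
parameter recovery is a well-posed round trip.

Sampling is an adaptive Metropolis-within-Gibbs scheme, chosen because it
makes runs bitwise reproducible for a fixed seed and needs no external
sampling engine:

1. a vectorized per-subject random-walk update of `z` in two blocks
   (k-dimensions, β-dimensions) — subjects are conditionally independent
   given the hyperparameters, so all subjects update in one step;
2. scalar random-walk updates of each hyperparameter (μ, log σ), with the
   half-normal prior's Jacobian on the log scale;
3. an ancillarity–sufficiency interweaving (ASIS) step: holding the
   constrained subject effects fixed, μ is redrawn from its conjugate
   normal conditional and log σ by a Metropolis step, after which `z` is
   back-transformed. The likelihood is unchanged, and this step is what
   makes the group-level parameters mix well — without it split-R̂ for the
   hyperparameters stays far above 1.05 on small data sets.

Proposal scales adapt during warmup only (diminishing Robbins–Monro
adaptation, targets 0.3 for the vector updates and 0.44 for scalars) and
are frozen afterwards, so retained draws form a valid Markov chain.
Defaults mirror the analysis configuration: 4 chains × 2000 iterations,
1000 warmup, 4000 retained draws. Initialization jitters around the prior
means with up to 5 re-initializations if the likelihood is non-finite.

Convergence is split-R̂ on retained draws (plain, not rank-normalized),
computed for every hyperparameter and for subject-level parameters on the
log scale; a fit is "converged" when all values are < 1.05. Zero-variance
draws define R̂ = 1 with a warning. Subject point estimates are posterior
means on the constrained scale.

## Model comparison and validation

LOOIC = −2·elpd_loo with elpd estimated by Pareto-smoothed importance
sampling on the pointwise log-likelihood matrix (smoothing via
`arviz.psislw`, draws on the last axis). The relative MCMC efficiency
passed to the smoother is estimated from the effective sample size of an
even subsample of pointwise columns. Trials whose likelihood is constant
across draws (e.g. a near-ceiling participant's easy cells, where every
draw gives p ≈ 1) have zero-variance importance ratios that the smoother
cannot fit; uniform weights are exact there and are substituted. Pareto
k > 0.7 is reported as a warning fraction, not a failure. With a
random-walk sampler the retained draws are autocorrelated, so the high-k
fraction runs higher than NUTS users may expect; the brute-force
leave-one-out refit oracle in the test suite bounds the resulting error
(PSIS elpd within 2·SE of exact LOO on a 5-subject × 30-trial data set).

Posterior predictive checks simulate choices (including Bernoulli noise)
for every fitted trial from ≥500 evenly thinned posterior draws and
compare observed per-cell costly-choice proportions against the central
95% predictive interval of the 50 design cells per task.

Parameter recovery fixes the population hyperparameters at their
posterior means, draws a fresh cohort of the same size from the implied
log-normal population, simulates choices on a generated design, refits the
same model, and reports (a) whether each group-level 95% HDI of the
original fit contains the refit's posterior-mean estimate and (b) Pearson
correlations between true and recovered subject parameters. A single
replicate cohort is used. HDI is the shortest interval at the stated mass
(via `arviz.hdi`).

## Experimental design generator

Each task has 150 trials: 3 blocks × 50, every (cost × reward ×
recipient) cell exactly 3 times, no recipient more than 4 consecutive
trials, and the mean cost level of **every** rolling 5-trial window in
[2, 3] (the strictest reading of the fatigue constraint; the disjoint
mini-block reading is implied by it). Because the balanced cells make the
overall mean cost exactly 3, the rolling constraint forces every aligned
mini-block of five to sum to exactly 15; the generator therefore samples
each mini-block as a permutation of (1..5), uniformly among those whose
boundary-crossing windows also satisfy the constraint, then assigns
recipients under quota and run-length constraints and permutes rewards
within (cost, recipient) groups. A consequence worth knowing: the
permutation-chain has low-entropy absorbing regions, so cost sequences
are more regular than an unconstrained shuffle — the printed constraint
set, not the generator, is what forces this. Construction is
rejection-based with bounded restarts and never relaxes a constraint;
an independent validator recounts all three constraints directly.

Time-level calibration interpolates three equidistant values between a
low and a high indifference point in [3, 27] s. The adaptive staircase
that would locate those points in the lab is replaced by a deterministic
bisection against a stylized agent (linear time cost, fixed effort cost),
accurate to ±0.5 s, since only the resulting 5-level grid feeds any
downstream computation; an agent who prefers one option over the whole
range yields the boundary with a warning.

## Synthetic cohort generator

Defaults are the study conditions: 74 participants × 2 tasks × 150
trials, omission rate 0.003, effort-execution failure rate 0.055 on
chosen-costly effort trials (time-task waits always complete), effort
data generated from `parabolic-2k2b` and time data from
`hyperbolic-2k2b`. Population log-means/SDs were chosen once so the
simulated behaviour reproduces the magnitudes that characterize this
paradigm — costly-choice rates around 60–70% (effort) and ~75–85% (time),
stronger discounting of environmental rewards, a heavy-tailed time-task
k distribution producing a subgroup of near-always-waiting (ceiling)
participants, and right-skewed individual differences:

| task | k_self | k_env | β (both) |
|---|---|---|---|
| effort | LogN(log 0.25, 0.7) | LogN(log 0.35, 0.7) | LogN(log 2, 0.5) |
| time | LogN(log 0.25, 1.5) | LogN(log 0.40, 1.5) | LogN(log 3, 0.6) |

Subject log-parameters share a common individual component across tasks
(`cross_task_correlation`, default 0.7), so cross-task Kendall
correlations of discounting tendencies are positive as in real cohorts.
The 12-item policy-support questionnaire (Likert 1–5) discretizes a
latent normal whose mean shifts with the standardized asymmetry
`k_self − k_env` times `questionnaire_coupling` (default +0.8; the sign
is configurable because the direction of this association is a
substantive choice, not a formal one).

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: the ceiling share tops out near ~20% of
participants (a single log-normal cannot produce a 40% ceiling share
while keeping mean waiting rates near 80%; a mixture would); decision
times are schema-filler (shifted log-normal, no downstream inference);
force traces, subjective effort ratings and the climate-beliefs battery
are out of scope; and real participants are not softmax agents — model
misspecification, session effects and strategic behaviour are absent by
construction.

## Statistical conventions

- Wilcoxon signed-rank: V = sum of positive-difference ranks; zero
  differences dropped, midranks for ties; exact p (sign-pattern
  distribution via polynomial convolution) for n ≤ 25 without ties,
  otherwise normal approximation with tie correction and continuity
  correction. The headline asymmetry test is one-tailed for
  k_env > k_self.
- Kendall's τ is tau-b (tie-corrected; scipy), exact p for small
  untied samples.
- Paired t is classical with df = n − 1; identical pairs define t = 0.
- Proportions are computed at full precision and reported as percentages;
  "average" choice proportions are participant means (each participant's
  proportion averaged), with trial-pooled values also available.

## Problem sizes used by the checks

Simulation-backed checks run at the smallest scale that still decides
the property: likelihood and nonparametric oracles on randomized
fixtures (seconds); exact-LOO comparison on 5 subjects × 30 trials;
12-model recovery on 20 subjects × 150 trials with 2 chains × 1000
iterations; parameter recovery at the full 74 × 150 with 2 chains × 1000.
`scripts/acceptance.py` fits the winning models at the default
4 × 2000 configuration and the 12-model comparison at 20 subjects.

## Known limitations

- The sampler is random-walk based: effective sample sizes per draw are
  far below NUTS; defaults compensate with cheap iterations. Heavier
  tails in the time task slow β mixing for ceiling participants.
- PSIS diagnostics inherit that autocorrelation (higher Pareto-k
  fractions); LOOIC differences between well-separated models are robust
  to this, near-ties are not.
- Joint-k fits define no discounting asymmetry; `k_difference` refuses
  them rather than returning zeros.
- The design generator implements the strict rolling-window reading of
  the fatigue constraint; if the original experiment used disjoint
  mini-blocks only, real sequences are less regular than generated ones.
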