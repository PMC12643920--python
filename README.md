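# ecocost

Analysis pipeline for cost-incurring decision experiments that compare
**self-benefitting** and **pro-environmental** motivation: participants
repeatedly choose between a no-cost baseline option worth 1 credit and a
costly option — exerting grip force (effort task) or waiting (time task) —
for a larger reward (2–10 credits), with the reward going either to
themselves or to a CO₂-reduction donation.

The package provides, as tested, reusable code:

- the experimental design (5 cost × 5 reward × 2 recipient cells, 150
  pseudorandomized trials per task with fatigue and recipient-run
  constraints, individual effort/time calibration),
- a synthetic-cohort generator with subject-level heterogeneity,
  omissions, execution failures and a policy-support questionnaire,
- hierarchical Bayesian estimation of **12 discounting models**,
- PSIS-LOO model comparison, posterior predictive checks and parameter
  recovery,
- the descriptive and nonparametric statistics of the behavioural results.

## The model

The subjective value of the costly option discounts the reward *R* by the
cost *C* (cost level 1–5) through one of three families

| family | SV |
|---|---|
| linear | `SV = R − k·C` |
| parabolic | `SV = R − k·C²` |
| hyperbolic | `SV = R / (1 + k·C)` |

and choices follow a softmax on the value difference with inverse
temperature β:

`P(costly) = 1 / (1 + exp(−β·(SV_costly − SV_baseline)))`,  `SV_baseline = 1`.

The discount rate *k* and β are each either shared across recipients
("joint") or separate for self vs environment trials, giving 3 × 2 × 2 =
12 models (canonical names like `parabolic-2k2b`). Parameters are
estimated hierarchically: subject-level log-parameters are drawn from
normal populations (`mu ~ N(0,1)`, `sigma ~ HalfNormal(0.5)` priors),
sampled by an adaptive Metropolis-within-Gibbs scheme with an
interweaving (ASIS) step, 4 chains × 2000 iterations (1000 warmup,
4000 retained draws), convergence checked by split-R̂ < 1.05. Models are
compared by LOOIC = −2·elpd_loo (PSIS).

## Worked example

```python
import ecocost as ec

# simulate a cohort with the study's structure (74 x 2 tasks x 150 trials)
cfg = ec.CohortConfig(n_subjects=74, seed=1)
trials, truth = ec.simulate_cohort(cfg)

# descriptive behaviour
cp = ec.choice_proportions(trials, ec.SummaryFilters(task="effort", recipient="environment"))
print(f"costly choices, effort/environment: {100 * cp.participant_mean:.1f}%")

# fit the winning effort model and test the self/environment asymmetry
fit = ec.fit_model(trials[trials.task == "effort"], "parabolic-2k2b",
                   config=ec.McmcConfig(chains=2, iterations=1000, warmup=500, seed=1))
est = ec.subject_point_estimates(fit)
V, p = ec.wilcoxon_signed_rank(est.k_self, est.k_env, alternative="less")
print(f"max R-hat {fit.max_rhat():.3f};  Wilcoxon V = {V:.0f}, one-tailed p = {p:.4f}")
```

Output:

```
costly choices, effort/environment: 60.1%
max R-hat 1.098;  Wilcoxon V = 818, one-tailed p = 0.0011
```

The 60.1% is the mean over participants of each participant's
costly-choice proportion on environment trials; the one-tailed Wilcoxon
tests whether environmental rewards are discounted more steeply than
self rewards (k_env > k_self) — here clearly so, by the generator's
construction.

An equivalent shell workflow is available through the `ecocost` CLI
(`simulate`, `fit`, `compare`, `recover`, `ppc`, `summarize`); run
`ecocost --help`.

The estimator also speaks scikit-learn:

```python
model = ec.HierarchicalDiscountingModel(model="hyperbolic-2k2b", seed=0)
model.fit(trials[trials.task == "time"])
model.predict_proba(...)  # posterior-mean P(costly) per trial
```

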