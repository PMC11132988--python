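# dynaphen — dynamic computational phenotyping of human cognition

A **computational phenotype** is the vector of fitted cognitive-model
parameters that characterizes an individual — learning rates, risk
attitudes, evidence-accumulation rates, lapse probabilities. When the same
battery of tasks is administered weekly for months, these parameters
drift: some of that drift is measurement noise, some is practice, and
some tracks the participant's affective state. `dynaphen` is a toolbox
for separating those sources. It is aimed at computational-psychiatry and
cognitive-modelling researchers who run (or simulate) longitudinal task
batteries and want principled answers to "how stable is this parameter,
and what moves it?".

## What is inside

**Seven trial-level task models** (likelihoods with analytic gradients +
matched simulators), parameterized by the phenotype θ:

| task | model | phenotype parameters |
|---|---|---|
| `gng` Go/No-go | Pavlovian reinforcement learning with context-coded neutral outcomes | b, π, ε, ρ_rew/pun, ρ_neut, ξ |
| `cd` Change detection | per-item maximum-absolute-difference observer, set-size-linear σ(N), θ(N) | σ₀, θ₀ + slopes |
| `rdm` Random dot motion | drift diffusion, drift linear in coherence | α, τ, δ |
| `lt` Lottery ticket | risk-sensitive utility U = Σ pᵢxᵢ^ρ + softmax | ρ, β |
| `itc` Intertemporal choice | hyperbolic discounting V = A/(1+kD) + softmax | k, β |
| `tab` Two-armed bandit | Kalman learner, probit in V, RU, sign(V)/TU | w_V, w_RU, w_sTU |
| `nc` Numerosity comparison | Weber-scaled Gaussian number noise | w |

**Three hierarchical Bayesian models** over weekly phenotypes y_t^s
(unconstrained space, one hierarchy per parameter):

* *independent* — y_t^s ~ N(μ^s, σ), μ^s ~ N(μ^g, η_g); sessions
  exchangeable within participant;
* *reduced* — y_t^s ~ N(μ^g, σ); no participant level (a deliberately
  misspecified baseline);
* *dynamic* —
  y_t^s ~ N(μ^s + δ_p^s (1 − t^(−b^s)) + δ_v^s v_t^s + δ_a^s a_t^s, σ),
  with a plateauing power-law practice term (exponent bounded in
  (e⁻², e)), valence/arousal state terms scaled as population fractions
  δ_i ∈ (−1, 1) of the participant baseline, and Gaussian session noise.

Fitting uses a hand-written adaptive HMC sampler (4 chains × 1000/1000 by
default). The default path is a fast two-stage scheme — per-session
penalized MAP with full Laplace covariance, then exact marginalization of
the latent sessions inside the Gaussian hierarchy — with the full joint
fit available via `two_stage=False`.

**Psychometrics**: bootstrapped ICC(2,1) (complete-case and first-N_max
variants), the fixed-phenotype reliability-ceiling experiment, relative
contributions (RC) of practice/valence/arousal/noise, probability of
direction (PD) with graded labels, and saturating power-law practice fits
with session-order permutation tests.

**Synthetic cohort**: the study design is generated end to end —
phenotype trajectories from the dynamic generative model, trial data per
the printed task designs (240 gng, 200 cd, 384 rdm, 30 lt, 27 itc,
300 tab, 160 nc trials per week), a 35-item survey driven by two latent
affective factors, and configurable missingness — with every generative
term retained as ground truth.

## Worked example

```python
import numpy as np
from dynaphen import (CohortConfig, generate_cohort, fit_model, ChainConfig,
                      to_phenotype_matrix, bootstrap_icc, probability_of_direction,
                      compute_state_components, normalize_states,
                      relative_contributions)

cfg = CohortConfig(n_participants=20, n_weeks=8, tasks=("nc",),
                   delta_p=0.6, delta_v=0.35, delta_a=0.15)
cohort = generate_cohort(cfg, seed=7)
states = normalize_states(compute_state_components(cohort["survey"]))
fit = fit_model("dynamic", "nc", cohort["trials"]["nc"], states=states.df,
                seed=7, chains=ChainConfig.scaled_down())

pd_res = probability_of_direction(fit.flat("delta_p")[:, 0], name="practice")
print(f"practice effect: PD = {pd_res.pd:.1f} ({pd_res.label}), "
      f"posterior mean delta_p = {fit.posterior_mean('delta_p')[0]:+.2f}")
print("median RC:", dict(relative_contributions(fit).median_rc("w").round(2)))
mat = to_phenotype_matrix(fit, override=True).matrix("nc", "w")
icc = bootstrap_icc(mat.to_numpy(float), seed=7, parameter="w")
print(f"ICC(2,1) of w: median {icc.median:.2f} "
      f"(IQR {icc.iqr[0]:.2f}-{icc.iqr[1]:.2f}, n = {icc.n_participants})")
```

prints

```
practice effect: PD = 100.0 (certainly existing), posterior mean delta_p = +0.60
median RC: {'arousal': 0.06, 'noise': 0.26, 'practice': 0.27, 'valence': 0.4}
ICC(2,1) of w: median 0.51 (IQR 0.42-0.58, n = 20)
```

The injected practice fraction (0.6 of the baseline) is recovered exactly
with a certainly-existing PD; the relative contributions split the weekly
variability of the Weber fraction among the injected sources; and the
week-to-week ICC is moderate because the dynamic effects make the
phenotype genuinely non-stationary.

A command-line pipeline wraps the same stages:

```bash
dynaphen simulate --config cohort.toml --seed 7 --out data/
dynaphen states   --data data/ --out states/
dynaphen fit      --task nc --model dynamic --data data/ \
                  --states-file states/states.csv --out fits/
dynaphen analyze  icc --task nc --fit fits/ --out analysis/
```

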