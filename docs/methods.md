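# Methods

This note documents the models, the estimation machinery, the synthetic
cohort that the tests exercise, and the numerical and design choices that
were genuinely open. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Task likelihoods

Each task module exposes a likelihood, its analytic gradient in
constrained space, per-trial choice probabilities, and a simulator drawn
from exactly the generative process the likelihood scores.

**Go/No-go.** Within each block of 80 trials, four stimuli prescribe
Go/No-go responses in win or avoid-punishment contexts. Instrumental
values Q(a, s) and the Pavlovian stimulus value V(s) start at 0 per block
and follow Rescorla–Wagner updates of the *effective* outcome: rewards
+ρ_rew/pun, punishments −ρ_rew/pun, and neutral outcomes context-coded
(−ρ_neut in win conditions, +ρ_neut in avoid conditions) — participants
treat "nothing happened" as a loss where they hoped to win and as relief
where they feared to lose. Only the taken action's Q is updated; V(s) is
updated on every trial of its stimulus regardless of action (Pavlovian
value is stimulus-bound). Choice: p(Go) = (1 − ξ)·logistic(W_go − W_nogo)
+ ξ/2 with W_go = Q(go,s) + b + π V(s), W_nogo = Q(nogo,s). Gradients
propagate through the value recursion by forward accumulation.

**Change detection.** Per-item encoded difference D_i = d_i + η,
η ~ N(0, 2σ(N)²) (two noisy encodings per item); item flagged iff
|D_i| > θ(N); respond "different" iff any item flags. Colour differences
are circular hue distances in degrees treated as linear magnitudes inside
the Gaussian rule; σ and θ grow linearly with set size N ∈ {3,4,6,8}; the
multiple-target block (0–4 changed items at N = 8) uses the same
per-item rule.

**Random dot motion.** Wiener first-passage density with boundary α,
non-decision time τ (seconds), drift δ·coherence, unit diffusion and
unbiased start (accuracy coding: upper boundary = correct). The density
uses the dual small-time/large-time series with per-trial regime
selection at a 1e-7 absolute truncation target; gradients w.r.t. (v, α,
t) are obtained by differentiating the series term-wise and mapping
through the scaling identity f(t|0,α) = α⁻² f̃(t/α²). Trials without a
response inside 1,500 ms are excluded; during optimization, RT ≤ τ
contributes a steep smooth penalty that pushes τ back below the smallest
fitted RT (the likelihood itself is zero there).

**Lottery ticket / Intertemporal choice.** Closed-form utilities
(U = Σ pᵢ xᵢ^ρ; V = A/(1 + kD), delays in days, immediate option D = 0)
with logistic choice. Certain (p = 1) lottery trials are removed before
modelling.

**Two-armed bandit.** Kalman filter per arm (prior mean m₀, variance
s₀²; observation variance τ_R² for risky arms and τ_S² = 1e-6 as a
numerical stand-in for a deterministic arm), state reset at block
boundaries. Because the filter depends only on observed choices and
rewards, the regressors V, RU and sign(V)/TU are precomputed once and
the likelihood is an ordinary probit (sign(0) = 0).

**Numerosity comparison.** p(choose 1) =
Φ((a₁ − a₂)/(w·√(a₁² + a₂²))) from Weber-scaled Gaussian encoding noise.

Missing-response trials are kept in the files, excluded from every
likelihood, and counted (`n_dropped`).

## Statistical models

All hierarchies act on unconstrained phenotypes (log for positive
parameters, logit for unit-interval ones, identity otherwise; exact
bijections with analytic Jacobians). Each task parameter gets its own
hierarchy — the phenotype is a vector, and the models are written per
entry.

* Independent: y_t^s ~ N(μ^s, σ), μ^s ~ N(μ^g, η_g), with
  σ, η_g ~ HalfNormal(0,1) and μ^g ~ N(loc, 1).
* Reduced: y_t^s ~ N(μ^g, σ).
* Dynamic: the session mean adds δ_p^s (1 − t^(−b^s)) + δ_v^s v_t^s
  + δ_a^s a_t^s. Population fractions δ_i = 2Φ(δ_i^prior) − 1 with
  δ_i^prior ~ N(0,1), and δ_i^s = δ_i·μ^s — effects scale with the
  participant baseline, so they vanish for baselines near zero (a model
  property, documented rather than patched). The practice exponent is
  b^s = exp(−2 + 3·logistic(z^s)), which keeps it strictly inside
  (e⁻², e) and leaves sampling smooth; z^s is partially pooled with a
  Normal(κ_b, ω_b) population prior, κ_b ~ N(0,1), ω_b ~ HalfNormal(0,1).
  The time index t is the calendar week (1..12), not the count of
  attended sessions; missing weeks simply contribute no likelihood.

One deliberate re-centering: the hyperprior on μ^g is N(loc_d, 1) where
loc_d is the parameter's documented reference value (e.g. log 0.35 s for
τ), and sampling starts with μ^g = loc_d and every other quantity at 0 in
the unconstrained space. This is the zero-initialized N(0,1) prior in a
shifted coordinate system; without the shift, a τ initialized at exp(0) =
1 s would start outside the support of the RT likelihood.

## Estimation

No probabilistic-programming backend is used; sampling is a self-contained
adaptive Hamiltonian Monte Carlo: dual-averaging step size (target
acceptance 0.8), diagonal mass matrix estimated from the middle of
warmup, trajectory length drawn uniformly from 1..64 leapfrog steps each
iteration (randomization suppresses periodic-orbit resonance), and
divergences flagged when the Hamiltonian error exceeds 1000. The default
contract is 4 chains × 1,000 warmup + 1,000 kept draws; a scaled-down
2 × 500/500 configuration is used for simulation studies. Convergence is
summarized by split R-hat and ESS (via `arviz`) over the hyper-level
quantities plus the divergence count; phenotype extraction refuses on a
failed gate unless overridden.

Two fitting paths:

* **Two-stage (default).** Each observed session is summarized by a
  penalized MAP estimate of its unconstrained phenotype (weak
  N(loc, 2.5²) penalty; L-BFGS with analytic gradients) together with the
  full Laplace covariance (central-difference Hessian, eigenvalues
  clipped to [0.02², 5²]). The Gaussian pseudo-likelihood
  ŷ_i ~ N(y_i, Σ_i) is then conjugate to the hierarchy, and the latent
  sessions are marginalized exactly: ŷ_i ~ N(mean_i, Σ_i + diag(σ²)).
  HMC runs over hyper-level quantities only (a few dozen to a few hundred
  dimensions, no funnels), and session phenotypes are recovered by exact
  conditional draws per kept draw. Keeping the full Σ_i matters: in
  tasks whose parameters trade off within a session (set-size intercepts
  vs slopes; learning rate vs effect sizes), the diagonal approximation
  discards exactly the information the hierarchy needs.
* **Joint** (`two_stage=False`): session phenotypes stay latent and the
  trial likelihoods enter the sampler directly, in a non-centered
  parameterization. This is the exact model; it is exercised on small
  problems in the tests and agrees with the two-stage path on group-level
  posteriors within Monte Carlo error.

All log-joint gradients — including through the task likelihoods, the
constraining transforms, the practice curve and the Φ-mapped fractions —
are analytic and validated against central finite differences.

## Survey states

Responses (35 numeric items; the free-text item is excluded) are pivoted
to a (participant, week, day) × item matrix; rows with any missing item
are dropped; each column is z-scored with population (ddof = 0) scaling —
so duplicating every row leaves scores untouched — and a two-component
PCA is run. Components are oriented deterministically by marker items
(positive-emotion items load positively on the valence component,
affect-intensity items on arousal). Daily scores are averaged within
week, missing weeks are linearly interpolated per participant *after*
the PCA (edges hold the nearest observed value), and the dynamic-model
regressors are normalized within participant to span [−1, 1] (constant
series map to 0).

## Synthetic cohort

The generator composes ground-truth trajectories exactly as the dynamic
model assumes (every term stored separately), simulates all seven tasks
at the printed weekly trial counts, and produces ordinal survey items
from two latent affective factors.

* **Scale.** Desk scale is 20 participants × 8 weeks (the default used
  throughout the tests and the acceptance script, chosen so the whole
  suite runs in minutes on one CPU); the full 90 × 12 design is
  `CohortConfig.full_scale()`.
* **Reference parameters** (unconstrained locations) are chosen to give
  realistic behaviour: rdm accuracy rising from ~0.6 at 5% coherence to
  ~0.99 at 50%; change-detection false-alarm rates of 5–25% with hits
  near 0.9; gng learners above the 0.55 accuracy criterion; nc accuracy
  ~0.75.
* **Stability calibration.** The session-level σ of each parameter is
  set from its published test-retest stability: with ICC ≈
  η²/(η² + σ²), σ = η·√(1/ICC − 1). The cohort therefore reproduces the
  study's stability profile — a nearly frozen reward/punishment effect
  size (ICC 0.99) next to a wandering lapse rate (0.45).
* **States.** Latent valence/arousal follow a per-participant AR(1)
  week-to-week process (coefficient 0.5) to emulate mood persistence;
  the statistical models make no such assumption — it is generator-only
  structure. Survey items mix the two factors (including cross-loading
  "mood/energy" items) with Gaussian noise and 7-point binning.
* **Missingness** removes whole participant-weeks at a configurable
  rate, optionally resampling so everyone still passes inclusion.

What passing tests on this cohort do *not* show about real data: the
generator is the dynamic model plus AR(1) states — real phenotype
dynamics need not follow a power law, real surveys have item-specific
response styles and missingness that is not completely at random, and
real task data contain sequential RT dependencies, day-of-week effects
and strategy shifts that no module here emulates.

## Psychometrics

* **ICC(2,1)** — two-way random-effects, absolute-agreement, single
  measurement, from the ANOVA mean squares; complete matrices only
  (complete-case filtering, or truncation of every participant to the
  first N_max observed sessions with the study's per-task N_max values).
  Bootstrap resamples participants (1,000 draws, seeded).
* **Ceiling experiment** — agents with session-constant phenotypes are
  simulated and refitted under both the independent and reduced models;
  the gap between the two ICCs isolates what the participant level of
  the hierarchy contributes to measured stability.
* **Relative contributions** — posterior-mean time series of each
  dynamic term per participant (unconstrained space, observed weeks
  only); RC_k = sd_k / Σ sd_i over
  {practice, valence, arousal, noise}; the constant baseline term has
  zero spread and is excluded. Participants with fewer than two observed
  weeks are dropped with a warning.
* **Probability of direction** — percentage of the posterior sharing
  the median's sign, labelled at 95/97/99/99.9 (uncertain / possibly /
  likely / probably / certainly existing).
* **Practice curves** — ŷ(t) = A − B·t^(−C), fitted by a coarse grid
  over C (A, B closed-form per C) polished by least squares. The
  permutation test uses the grid-maximized R² as its statistic for both
  the observed and the 10,000 permuted orderings (exchangeable by
  construction) with add-one smoothing, p = (1 + #{perm ≥ obs})/(1 + n).

## Known limitations

* The two-stage path relies on the Laplace approximation; for sessions
  with few trials and skewed posteriors (inverse temperatures at 27–30
  trials, lapse rates) it costs recovery accuracy relative to the joint
  fit, and in the reliability-ceiling experiment it leaves the
  low-trial-count tasks slightly below the ceiling a publication-scale
  joint fit attains.
* Weakly identified session-level quantities remain weakly identified:
  under the stability-calibrated cohort, the gng lapse rate and the cd
  threshold slope sit near correlation ~0.45–0.55 with their session
  truths — an information ceiling, not an estimator defect.
* The inclusion gap rule counts missing runs between a participant's
  first and last observed week; leading runs (late entry) and trailing
  runs (drop-out) are not counted as gaps.
* PD-based false-direction control is honest but stochastic: a
  zero-effect cohort still produces |z| ≥ 2.3 apparent effects at
  roughly the nominal rate, so small replicate counts give noisy
  false-direction estimates.
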