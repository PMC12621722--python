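# Methods

## The behavioral model

`pglearn` targets trial-by-trial choice data from two-alternative
forced-choice (2AFC) training: on trial `t` an animal sees a stimulus of
contrast `c_t ∈ [0, 1]` on the left or right, chooses a side
`y_t ∈ {L, R}` (coded −1/+1 throughout), and is rewarded `r* > 0` when the
choice matches the stimulus side.  The package infers the *learning rule*
that moved the animal from chance to proficiency.

The decision policy is a Bernoulli GLM,

    p(y_t = R | w_t, x_t) = 1 / (1 + exp(−w_tᵀ x_t)),

over M = 5 regressors: a bias (always 1), left stimulus contrast, right
stimulus contrast, the previous choice, and the previous correct side
(both ±1, reset to 0 at each session start).  Learning is drift of the
policy weights,

    w_{t+1} = w_t + α ⊙ (r_t·1 − β) (1 − p(y_t|w_t,x_t)) y_t x_t − Q ⊙ w_t + ε_t,

a REINFORCE policy-gradient step with per-regressor learning rates `α`,
reward baselines `β`, weight decay `Q`, and Gaussian dynamics noise
`ε_t ~ N(0, diag(σ_t²))`, where `σ_t` is `σ_day` on session boundaries and
`σ` within sessions (all per-regressor, elementwise products throughout).
Model variants nest each other: `noise_only` (α = Q = 0; a pure
random-walk weight model in the PsyTrack spirit), `scalar_pg` (all
parameters shared across regressors), `vector_pg` (the full parameter
set), `dynamic_rate` (a latent scalar gain `a_t` on the learning term with
random-walk prior `a_{t+1} = a_t + N(0, σ_α²)`, `a_1 ~ N(α_0, σ_α²)`),
and `dynamic_baseline` (latent per-regressor baselines with random-walk SD
`β_σ`).

The action-value alternative (`TDRLParams`, `TDRLLearner`) perceives the
signed contrast through Gaussian noise `m_t ~ N(s_t, σ_m²)`, chooses R
when the percept clears the criterion `σ_m Φ⁻¹(V_L/(V_L+V_R))`, and
TD-updates the chosen value with a belief-weighted prediction error
`V_y ← V_y + λ (r − V_y Φ(y·s/(2σ_m))) + V_y φ_{σ_m}(s) ε`.
Marginalizing the percept makes its choice rule a probit GLM in
`s/σ_m` — the policies of the two families are equivalent; they differ in
the latent update dynamics and in how noise enters them.

### Key parameters and defaults

| parameter | meaning | default |
|---|---|---|
| `alpha` | learning rate per regressor (per trial) | fit; sims use 0.02–0.15 |
| `beta` | reward baseline; negative values reinforce errors | fit; sims use −0.2…−0.5 |
| `qdiag` | weight decay (forgetting) per trial | fit; sims use ~0.005 |
| `sigma` | within-session dynamics noise SD | fit; sims use 0.08 |
| `sigma_day` | across-session noise SD | fit; sims use 0.15 |
| `rstar` | reward magnitude | 1.0 |
| `w1_mean`, `w1_sd` | initial-weight prior | 0, 1 |
| `n_particles` | bootstrap-filter size | 1000 |
| `heldout_frac` | trials excluded from the training objective | 0.1 |
| `sigma_m` | TD percept-noise SD (contrast units) | fit; init 0.3 |
| `td_rate` | TD step size | fit; init 0.5 |

## Inference

The marginal likelihood integrates the latent weight (and gain/baseline)
trajectories out of the choice sequence.  A bootstrap particle filter
estimates it: particles propagate through the learning rule conditioned on
the animal's *realized* choices and rewards, are weighted by the Bernoulli
likelihood of each observed choice, and are systematically resampled when
the effective sample size falls below half the particle count.  Before
each resampling the particles are ordered by their current logit, which
keeps the surviving set (and hence the likelihood surface under common
random numbers) as continuous in the parameters as resampling allows.

Held-out trials (10% by default, uniformly at random) contribute no
likelihood to the training objective, but the realized choice still drives
the particle dynamics — the animal experienced the trial, so the learning
rule must see it.  Their predictive probabilities come from the particle
mixture and are reported separately; "full-trajectory" log-likelihoods
always include them.

Smoothed trajectories come from ancestral-lineage tracing by default
(free, but early-trial uncertainty collapses once lineages coalesce on
long series) or from a backward-simulation pass (FFBSi) against the
Gaussian transition density (`smooth_posterior(method="backward")`), which
is what coverage-sensitive analyses should use.

### Maximum likelihood

All randomness of the filter is pre-generated from one seed (the
state-noise normals and resampling uniforms), so the likelihood is a
deterministic function of the parameters during an optimization (common
random numbers).  That surface is still non-smooth: perturbing a noise
scale rescales every particle increment and reshuffles resampling, which
produces nat-scale jitter between neighboring parameter points.  Gradient
and line-search methods stall on it (we verified L-BFGS-B with central
differences terminates after a handful of iterations), so the default
optimizer is derandomized cyclic coordinate descent: for each
unconstrained coordinate, scan nine points across a bracket (half-width
1.5), keep the best, refine locally, and shrink the bracket by half on
each pass.  Coordinates are visited in identifiability order (σ, α, β, Q,
σ_day, then latent-dynamics parameters).  Positive parameters are
softplus-transformed; `β` and `α_0` are unconstrained; learning rates can
be released to negative values with `constrain_alpha=False`.  Multi-start
(default 3) jitters the starting point; the best optimum is kept, and the
reported log-likelihoods are recomputed at the optimum with fresh filter
randomness.  L-BFGS-B with central differences and bounded-Brent
coordinate descent remain available as `optimizer="lbfgs"` /
`"coordinate"` for smoother problems.

Parameter uncertainty comes from particle-marginal Metropolis–Hastings:
Gaussian random-walk proposals in the unconstrained coordinates, accepted
against a fresh-randomness filter estimate of the likelihood that is
carried with the chain state (pseudo-marginal correctness).  The scalar
proposal scale adapts toward ~25% acceptance during the burn-in quarter,
then freezes.

## Learning/noise decomposition

Given fitted parameters and an inferred (posterior-mean) trajectory
`ŵ_{1:T}`, the learning component replays the rule deterministically from
`ŵ_1` with the realized choices; the per-trial residual is
`ε̂_t = (ŵ_{t+1} − ŵ_t) − Δlearn_t`, with `Δlearn_t` the drift evaluated at
`ŵ_t` (the inferred weights, not the rollout).  The learning fraction is
the mean over trials of `‖Δlearn_t‖ / (‖Δlearn_t‖ + ‖ε̂_t‖)`, taken as 0
when both norms vanish; a ratio-of-sums variant and projection/cosine
alternatives are reported alongside.  Norms at float-recomputation level
(≤1e−10 of the largest update) are treated as zero so the analytic
endpoints are exact: 0 for any model with `α ≡ 0`, 1 for a noiseless
deterministic learner.  Note the 0-when-both-zero convention interacts
with `β = 0`, under which correct-only learning prescribes *no* update on
error trials; endpoint demonstrations therefore use a non-zero baseline so
the rule moves on every trial.

Cohort summaries: per-animal stimulus weights re-labeled
preferred/non-preferred by the larger fitted learning rate, trial-warped
(linear time rescaling to [0,1] + linear interpolation) and averaged, with
a seeded animal↔parameter permutation as control; the
reward-after-error statistic `E[r_{t+1} | r_t = 0]` vs. `E[r_t]` over
within-session pairs; residual-norm vs. `‖σ̂‖` correlation across animals;
and for dynamic-rate fits the warped cohort mean of
`log α̂_t − log α̂_1` (floored at 1e−6) with pointwise one-sample
t-statistics and its correlation with warped cumulative accuracy.

## Synthetic data

The simulator emulates staged rodent 2AFC training: sessions of a few
hundred trials; contrast set {1.0, 0.5, 0.25, 0.125, 0.0625, 0} with
harder contrasts unlocked at configurable session indices (default 0.25 at
session 6, 0.125 at 9, 0.0625 at 12, 0 at 15 — real protocols advance per
animal, so these are nominal), or a uniform no-curriculum schedule;
stimulus side Bernoulli(0.5).  On zero-contrast trials the rewarded side
is still drawn from the side distribution so every trial has a defined
correct side.  Choices are sampled from the generative policy itself, so
recovery studies are well-specified by construction.  What the generator
does **not** emulate: reaction times and wheel kinematics, engagement or
satiety states, per-animal curriculum advancement tied to performance, and
biased-block phases.  Passing tests therefore demonstrate correctness of
the inference machinery under the model class, not that real mice satisfy
the model.

Cohorts derive per-animal seeds from a master seed by counter-based
splitting, so enlarging a cohort never changes earlier animals.

## Numerical choices

- Choice probabilities clamped to [1e−12, 1−1e−12] before logs.
- Signed stimulus `s = contrast_right − contrast_left`.
- `σ_day` applies to the transition from a session's last trial into the
  next session's first.
- Held-out count is `round(fraction·T)` (banker's rounding), drawn without
  replacement.
- TD stochastic choice uses a symmetric lapse mixing the threshold rule
  with a fair coin — a deliberately simple stand-in for decision
  temperature; values are floored at 1e−6 to keep the criterion defined.
- The dynamic-rate gain is filtered in linear coordinates (particles may
  cross zero); log-differences are only taken for reporting, with the
  1e−6 floor.
- `α_0` and the global `α` scale are jointly redundant at initialization;
  both are kept free (as in the model definition) and the optimizer
  resolves the scale — interpret only the product / trajectory shape.

## Problem sizes in the test suite

Test and acceptance runs use desk-scale sizes chosen once: recovery
replicates use T = 3,200 trials, 250 particles, 2 coordinate-descent
passes; the noise-scale recovery uses T = 10,000 and 300 particles;
dynamic-rate step recovery T = 2,400 with 150 particles; model comparison
uses 5 simulated animals at T = 2,000 and 150 particles;
filter-vs-quadrature checks use T = 8 with 1,000 particles and 500
replicate filters.  Full-scale analyses should prefer the defaults
(1,000 particles, 3 starts, 3 passes).

## Known limitations

- The coordinate-descent optimizer recovers signs and noise scales well,
  but point estimates of weakly identified parameters (per-regressor
  `σ_day` with few session boundaries, `Q` vs. negative `β`, history
  regressor rates) carry large sampling error at desk-scale T; use the
  PMMH posterior SDs rather than point estimates for such claims.
- Ancestral-lineage smoothing degenerates at early trials on long series;
  use the backward pass when early-trial uncertainty matters.
- The TD model's supplement-level details (decision temperature, stimulus
  prior) are simplified to the threshold-plus-lapse rule described above.
- Likelihood comparisons between model families use equal data and masks
  but do not correct for parameter counts beyond the "matched number of
  weights" convention of comparing similarly sized variants.
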