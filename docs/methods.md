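# Methods

`sidetraj` implements hierarchical continuous-time state-space models for
routinely collected suicidal-ideation scores (summed SIDAS, an integer on
0–50) observed at irregular times, together with the Bayesian machinery to
fit them and to turn posterior draws into individual-level forecasts.

## Model

### Latent dynamics

Each individual *m* carries a latent, unbounded ideation state
*x<sub>m</sub>(t)* following one of two SDEs with exact transition laws:

* **Wiener** (continuous-time random walk):
  *x(t+Δ) | x(t) ~ N(x(t), e<sup>2φ₂</sup>Δ)*.
* **Ornstein–Uhlenbeck** (continuous-time autoregression): with rate
  θ = e<sup>φ₃</sup> and long-term constant φ₄,
  *x(t+Δ) | x(t) ~ N(φ₄ + (x(t) − φ₄)e<sup>−θΔ</sup>,
  e<sup>2φ₂</sup>(1 − e<sup>−2θΔ</sup>)/(2θ))*.

Time is measured in days; all gaps may be irregular and the transitions are
exact, so no discretisation error is introduced anywhere.  The initial
state is *x(0) = φ₁*; the baseline observation is noisy through the
observation model like every other observation.

Parameterisation keeps every individual parameter unbounded so that normal
random effects are well formed: φ₂ is the log of the diffusion SD per
√day and φ₃ the log mean-reversion rate per day.  (The log-SD rather than
log-variance convention for φ₂ is a package choice; it is exposed in one
place — the transition functions — should a different convention be
needed.)  The OU variance uses `expm1`, so rates down to ~10⁻⁸/day
reproduce the Wiener limit to full precision.

### Observation model

A latent value maps to the score scale through a scaled logistic link
*m(x) = 50·logistic(x)* (steepness configurable via `link_scale`, default
1), and the integer score is a **discretised normal** around *m(x)* with SD
`sigma_y`: interior bins integrate the density over (k−½, k+½] and the two
boundary bins absorb the tails.  Tail absorption (rather than renormalised
truncation) keeps the pmf exact, guarantees every score positive
probability for every finite latent state, and makes inverse-CDF sampling a
one-liner (round-half-up of a Gaussian draw, clipped into range).
`sigma_y` is a single population-level scale, fixed at 2.0 score units by
default and optionally sampled with a log-normal prior
(log σ_y ~ N(0, 1)); a shared noise scale is the parsimonious reading when
nothing suggests individual-specific measurement noise.

Log-pmf values are floored at log(tiny double) ≈ −708 so the likelihood is
finite for any finite state; the floor is unreachable for the 0–50 score
range at any plausible `sigma_y`.

### Model variants and random effects

Four catalogued variants span the fixed/random-effect choices:

| variant | process | baseline | diffusion | drift rate | constant |
|---|---|---|---|---|---|
| 1 | Wiener | random | fixed | — | — |
| 2 | Wiener | random | random | — | — |
| 3 | OU | random | random | fixed | random |
| 4 | OU | random | random | random | random |

Random-effect slots follow *φ<sub>m,j</sub> ~ N(μ_j, τ_j²)* with
semi-conjugate hyperpriors *μ_j ~ N(0, 5²)* and *τ_j² ~ InvGamma(2, 1)*
(configurable).  Fixed-effect slots hold one shared value with a N(0, 5²)
prior.

## Inference

The individual likelihood p(y|φ) has no closed form (nonlinear link,
discretised observations), so it is estimated unbiasedly by a **bootstrap
particle filter**: particles start at φ₁ at t = 0, propagate through the
exact SDE transition over each observation gap, are weighted by the
observation pmf, and are systematically resampled with a single uniform per
step.  The filter is a deterministic function of a fixed-shape block of
standard-normal auxiliary variables (propagation normals plus one normal
per step mapped through Φ to the resampling uniform).

Sampling uses a **correlated pseudo-marginal Metropolis–Hastings within
Gibbs** scheme:

1. *Individual step* — for each individual, a Gaussian random-walk proposal
   on the random-effect slots together with a Crank–Nicolson refresh of the
   auxiliary block, `u' = ρu + √(1−ρ²)ε`, ρ = 0.99 by default.  Correlating
   successive likelihood estimates cancels most of the estimator noise in
   the acceptance ratio, which is what lets ~100 particles suffice.
   Particles are sorted by state before resampling so the auxiliary-to-
   likelihood map stays nearly continuous in φ.  Proposal SDs are the
   current population SDs scaled by a per-individual multiplier adapted
   towards ~0.30 acceptance during burn-in only (the scale may depend on
   the population state because the proposal remains symmetric in φ).
   Optionally several sub-steps run per sweep to improve mixing.
2. *Fixed effects* — any shared parameter values get a joint pseudo-
   marginal MH update using the summed individual likelihoods at the
   current auxiliaries.
3. *Population layer* — exact Gibbs draws: normal full conditional for each
   μ_j, then inverse-gamma for τ_j².
4. *Observation SD* (optional) — a pseudo-marginal MH step on log σ_y.

Initialisation sets φ₁ from the inverse-linked first observation and the
remaining slots at the population means; this affects only warm-up.  Runs
are bit-reproducible from a single integer seed.

### Model comparison

WAIC on the deviance scale: lppd = Σ_i log(mean_s exp ll_si) via
log-sum-exp, penalty p = Σ_i var_s(ll_si) (the variance of the pointwise
posterior log-likelihood), WAIC = −2(lppd − p); lower is better.  The
pointwise unit is one observation (the filter's predictive increment).
Two practical points:

* Increments stored during sampling carry the chain's own particle noise,
  correlated with the accept/reject history; they are fine for monitoring
  but inflate the variance penalty.  Model comparison therefore recomputes
  the pointwise terms for a thinned set of posterior draws with fresh
  auxiliaries and a larger particle count (`pointwise_loglik`, 200–300+
  particles).
* Mirroring the analysis the WAIC table is computed on the subset of
  individuals with ≥ 10 observations (`--waic-min-obs`), where predictive
  increments are informative.

## Prediction

Forecasts are posterior predictive: for each retained parameter draw the
current latent state is sampled from the particle filtering distribution at
the last observation (not a point estimate), the latent SDE is stepped
exactly one day at a time over a 60-day horizon, and an integer score is
sampled each day.  Summaries:

* daily median and 68% / 95% equal-tailed intervals (ETI);
* **IHIP** — fraction of paths whose score strictly exceeds 20 on any day
  of the horizon;
* **FUT** — first day whose 95% ETI range exceeds 25 (half the score
  range), reported with a censored flag when no day crosses within the
  horizon;
* **V** — the 95% ETI range of the horizon-day score computed *within* each
  parameter draw, averaged across draws, with an 80% HDI over those
  per-draw ranges (computing the range per draw is what gives the HDI a
  well-defined distribution to summarise).

ETIs are empirical quantiles; HDIs use the sorted shortest-window
algorithm.  Dynamic updating freezes the population layer at marginal MAP
estimates (Gaussian-KDE modes of the population draws), refits only the
individual by CPM-MH, and forecasts from the last observation of the
prefix — population uncertainty is deliberately not propagated in this
mode, matching its intended use as a fast in-care update.

Covariate screening computes, per posterior draw, the Pearson correlation
across individuals between the draw's diffusion values and a continuous
covariate (or a difference of group means for a binary covariate), and
summarises the per-draw statistic by mean and 95% ETI.  The reported
uncertainty is therefore posterior uncertainty in the individual
parameters, not covariate sampling error.

### Worked example

Starting from score 2 (latent logit(0.04) ≈ −3.18) with diffusion
parameter −1.23, the latent trajectory after 7 days is
N(−3.18, (0.292·√7)²).  Mapping the one-sigma (68%) band through the link
gives scores 0.96–4.26, i.e. the integer range **[1, 4]** — a trajectory
starting at 2 diffuses to between 1 and 4 within a week under the default
configuration.  The credible level of this published range is not stated
anywhere we can check; the 68% band reproduces it exactly under the
package defaults, while the 95% band is [0, 8], so the package treats the
range as a one-sigma statement.

## Synthetic cohorts

The generator emulates the structure of measurement-based-care data:

* per-individual parameters drawn from the configured population normals;
* observation counts from a two-part law — probability 0.55 of exactly the
  2-observation minimum (making 2 the median), otherwise 2 plus a geometric
  tail calibrated so the mean count is 4.5;
* log-normal inter-observation gaps with median 35 days and log-SD 1.7.
  The empirical gap distribution is more asymmetric (IQR roughly 1–108
  days) than any log-normal allows; the law matches the median and the
  upper quartile (~110 days) and accepts a heavier lower quartile (~11
  days).  Early versions used a wider spread, which produced gaps of
  thousands of days — outside any plausible study window — and made
  particle filtering degenerate at high-diffusion parameter draws;
* a structural zero-ideation subgroup (26% of individuals score 0 at every
  observation regardless of their latent dynamics).

Structural zeros are generated but *not* modelled: the inference model is a
continuous-state model and does not capture the binary at-all/none aspect
of ideation, so recovery experiments default to `zero_fraction = 0`.
Synthetic cohorts also contain no informative-missingness mechanism: in
real monitoring data, entry times may correlate with state, which nothing
here emulates.  Passing tests therefore demonstrate correctness of the
machinery under the model's own assumptions, not robustness to those
real-data violations.

## Numerical and scaling choices

* Particle count defaults to 100 with ρ = 0.99; single observations at t=0
  are handled exactly (all particles coincide).
* Degenerate inputs: zero gaps give zero-variance transitions; duplicate
  (individual, time) records keep the last entry; residual same-day ties
  are offset by 10⁻³ days; scores at 0 or 50 are offset half a unit inward
  before link inversion.
* Effective-sample-size warnings fire when a filter's ESS drops below 10%
  of the particle count.
* Test and acceptance problem sizes are scaled-down study analogues chosen
  to exercise every claim at meaningful power: recovery uses 40 individuals
  × 20 observations with 1000-iteration chains; the model-selection
  direction uses ten replicate cohorts of 15 individuals × 14 observations
  with 500-iteration chains per variant.  At that cohort size the WAIC
  gap between the Wiener variants is usually decisive but single cohorts
  can flip: a handful of abrupt score jumps can dominate the variance
  penalty when per-individual diffusion posteriors are wide, so the
  direction stabilises only as the number of well-observed individuals
  grows toward the full-study scale.

## File formats

All artefacts are plain text.

* Observations CSV: `individual_id, time_days, sidas_total` (long format;
  time in real days since baseline, scores integer 0–50).
* Individual samples CSV (`samples_individual.csv`):
  `draw, individual_id, parameter, value` with parameter ∈
  `phi1..phi4`; one row per kept draw × individual × slot.
* Population samples CSV (`samples_population.csv`):
  `draw, parameter, value` with parameter ∈ `mu_phij`, `tau_phij`
  (random slots only) and `sigma_y`.
* WAIC table CSV: `variant, model_type, random_effects, waic, p_waic,
  seed, best` (random_effects as an R/F string per slot; exactly one
  `best=True` row).
* Predictive summaries JSON: `{"config": ..., "records": [...]}` where
  each record carries `horizon_days`, the five daily arrays
  (`daily_median`, `daily_eti68_lo/hi`, `daily_eti95_lo/hi`), `ihip`,
  `fut_days`, `fut_censored`, `v`, `v_hdi80`, `seed`, `individual_id` and
  (in dynamic-updating mode) `cut_time`.
* Truth sidecar JSON (simulate): seed, config echo, true population
  parameters, per-individual true parameters with structural-zero flags,
  and the cohort summary statistics.

## Known limitations

* The pseudo-marginal chain can stick for individuals whose data barely
  constrain the diffusion (all-zero or fully saturated score series);
  population estimates are robust to this, individual posteriors for such
  cases mostly return the prior.
* WAIC from estimated likelihoods retains a small upward penalty bias that
  shrinks with the particle count used in `pointwise_loglik`.
* Dynamic updating ignores population-parameter uncertainty by design.
* OU fits are substantially slower than Wiener fits (four parameter slots)
  and are the least exercised path in the test suite.
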