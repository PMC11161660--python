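# sidetraj

Continuous-time hierarchical trajectory models for suicidal-ideation
scores collected during routine clinical care.

## The problem

Measurement-based mental health care produces long, irregularly spaced
series of patient-reported scores — for suicidal ideation, the summed
SIDAS score (five items, total 0–50) — with most individuals observed only
a handful of times at gaps ranging from a day to several months.
Discrete-time models handle such data poorly; clinicians, meanwhile, need
*individual-level* forward-looking answers: how severe and how variable is
this person's ideation likely to be, and how soon should we observe them
again?

`sidetraj` addresses this with mixed-effects stochastic differential
equation models.  Each individual *m* has a latent state following either
a Wiener process (dx = e^{φ₂} dW, a continuous-time random walk) or an
Ornstein–Uhlenbeck process (mean-reverting to a constant φ₄ at rate
e^{φ₃}), observed through a logistic link onto (0, 50) and a discretised
normal around the linked mean.  Individual parameters get hierarchical
normal random effects, φ_{m,j} ~ N(μ_j, τ_j²).  Because the likelihood of
the discretised, linked observations is intractable, it is estimated
unbiasedly with a bootstrap particle filter, and the posterior is sampled
with a correlated pseudo-marginal Metropolis–Hastings-within-Gibbs scheme
(Crank–Nicolson refresh of the filter's auxiliary variables, ρ = 0.99).
Model variants are ranked by WAIC, and posterior predictive simulation
over a 60-day horizon yields three clinical summaries per individual:

* **IHIP** — probability of entering the high-ideation range (score > 20)
  on any day of the horizon;
* **V** — expected 95% ETI range of the score at the horizon (future
  observational variability), with an 80% HDI;
* **FUT** — first day the 95% ETI range exceeds half the scale (> 25), a
  recommended follow-up time.

A synthetic-cohort generator reproduces the statistical structure of such
data (skewed observation counts, log-normal gaps, a zero-ideation
subgroup, hierarchical effects), so the whole pipeline is testable with
known ground truth.  See `docs/methods.md` for the full model and the
numerical choices.

## Worked example

```python
import numpy as np
from sidetraj import CohortConfig, PopulationParams, SDETrajectoryModel, generate_cohort

cohort = generate_cohort(CohortConfig(
    n_individuals=20, zero_fraction=0.0, fixed_obs_count=10, seed=42,
    true_pop=PopulationParams(mu=np.array([-1.0, -1.2]),
                              tau=np.array([1.0, 0.5]), sigma_y=2.0),
))
model = SDETrajectoryModel(variant=2, iterations=600, burnin=200,
                           n_particles=100, random_state=0)
model.fit(cohort.dataset.frame)
print("population mean diffusion:", round(model.population_mean_.mu[1], 2))

summary = model.predict("ind0000")
print("IHIP:", round(summary.ihip, 3))
print("FUT:", summary.fut_days, "days", "(censored)" if summary.fut_censored else "")
print("V:", round(summary.v, 1), "score units")
```

Output (exact values reproduce with the seeds above):

```
population mean diffusion: -1.22
IHIP: 0.261
FUT: 19 days 
V: 27.5 score units
```

The fitted population mean diffusion (−1.22) recovers the generating
value −1.2 within posterior uncertainty.  For this individual the model
gives a 26% chance of entering the high-ideation range within 60 days,
its 95% band stays narrower than half the scale until day 19 (a
reasonable revisit interval), and the score 60 days out is expected to
span a ~28-unit 95% range.

The package's own in-text reference calculation: a trajectory starting at
score 2 with diffusion parameter −1.23 diffuses to the score range
**[1, 4]** within a week (one-sigma band):

```python
from sidetraj import diffusion_score_range
diffusion_score_range(start_score=2, phi2=-1.23, days=7, level=0.68)  # (1, 4)
```

A command-line workflow mirrors the analysis end to end:

```bash
sidetraj simulate --n-individuals 100 --seed 1 --out-dir data/
sidetraj fit      --data data/observations.csv --out-dir fit/ --model 2 --seed 1
sidetraj compare  --data data/observations.csv --out waic.csv --seed 1
sidetraj predict  --data data/observations.csv --samples-dir fit/ --out pred.json
sidetraj associate --samples-dir fit/ --covariates data/covariates.csv --out assoc.csv
```

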