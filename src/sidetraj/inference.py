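"""Particle-filter likelihood and correlated pseudo-marginal MCMC.

The hierarchical model
----------------------
Each individual m has a latent continuous-time process (Wiener or OU,
:mod:`sidetraj.latent`) parameterised by phi_m, observed at irregular times
through the ordinal observation model (:mod:`sidetraj.observation`).
Random-effect slots of phi_m follow population normals ``N(mu_j, tau_j^2)``;
fixed-effect slots share one value across the cohort.  The population means
get normal hyperpriors and the variances inverse-gamma hyperpriors, so the
population layer is semi-conjugate.

Inference
---------
The intractable individual likelihood ``p(y_m | phi_m)`` is estimated
unbiasedly by a bootstrap particle filter.  Individual parameters are
updated with a correlated pseudo-marginal Metropolis-Hastings step: the
filter's auxiliary Gaussian variables are refreshed by a Crank-Nicolson
autoregression with correlation ``rho`` close to one, so successive
likelihood estimates share most of their Monte-Carlo noise and the
acceptance ratio is far less noisy than with independent estimates.
Particles are sorted by state before systematic resampling to keep the
auxiliary-variable-to-likelihood map smooth.  Population means and SDs are
then drawn exactly from their semi-conjugate full conditionals (Gibbs);
fixed-effect values and (optionally) the observation SD get their own
pseudo-marginal MH updates based on the summed individual likelihoods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, ndtr

from .data import TrajectoryDataset
from .latent import ModelSpec, transition
from .observation import DiscretizedObservationModel, ObservationModelConfig, inverse_link

logger = logging.getLogger(__name__)

__all__ = [
    "AuxiliaryVariables",
    "ParticleFilterResult",
    "PopulationParams",
    "Hyperpriors",
    "SamplerConfig",
    "PosteriorSamples",
    "draw_aux",
    "refresh_aux",
    "particle_filter_loglik",
    "cpm_mh_individual_step",
    "gibbs_update_population",
    "run_mcmc",
    "run_individual_mcmc",
    "waic",
]


# --------------------------------------------------------------------------
# auxiliary variables


@dataclass(frozen=True)
class AuxiliaryVariables:
    """All randomness consumed by one particle-filter run, as Gaussians.

    ``particle_normals`` drives the particle propagation (one column per
    observation step); ``resample_normals`` is mapped through the normal CDF
    to give the single systematic-resampling uniform of each step.  Keeping
    the whole block Gaussian lets the Crank-Nicolson refresh preserve the
    marginal law exactly.
    """

    particle_normals: np.ndarray  # (n_particles, n_steps)
    resample_normals: np.ndarray  # (n_steps,)

    @property
    def n_particles(self) -> int:
        return self.particle_normals.shape[0]

    @property
    def n_steps(self) -> int:
        return self.particle_normals.shape[1]

    def resample_uniforms(self) -> np.ndarray:
        return ndtr(self.resample_normals)


def draw_aux(rng: np.random.Generator, n_particles: int, n_steps: int) -> AuxiliaryVariables:
    return AuxiliaryVariables(
        particle_normals=rng.standard_normal((n_particles, n_steps)),
        resample_normals=rng.standard_normal(n_steps),
    )


def refresh_aux(aux: AuxiliaryVariables, rho: float, fresh: AuxiliaryVariables) -> AuxiliaryVariables:
    """Crank-Nicolson update u' = rho*u + sqrt(1-rho^2)*fresh, elementwise.

    Preserves the standard-normal marginal for any rho in [0, 1]; rho=1
    reuses the block unchanged, rho=0 replaces it entirely.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    if fresh.particle_normals.shape != aux.particle_normals.shape:
        raise ValueError("fresh auxiliary block has mismatched shape")
    w = np.sqrt(1.0 - rho * rho)
    return AuxiliaryVariables(
        particle_normals=rho * aux.particle_normals + w * fresh.particle_normals,
        resample_normals=rho * aux.resample_normals + w * fresh.resample_normals,
    )


# --------------------------------------------------------------------------
# particle filter


@dataclass(frozen=True)
class ParticleFilterResult:
    """Likelihood estimate with per-observation predictive increments."""

    total_loglik: float
    increments: np.ndarray  # (n_obs,)
    final_particles: np.ndarray  # equally weighted filtering sample at last obs
    min_ess: float  # smallest effective sample size across steps

    def __post_init__(self) -> None:
        object.__setattr__(self, "increments", np.asarray(self.increments, float))


def _systematic_resample(weights: np.ndarray, u: float) -> np.ndarray:
    n = weights.size
    positions = (u + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions).clip(max=n - 1)


def particle_filter_loglik(
    times: np.ndarray,
    scores: np.ndarray,
    phi: np.ndarray,
    spec: ModelSpec,
    obs_model,
    aux: AuxiliaryVariables,
) -> ParticleFilterResult:
    """Bootstrap particle filter; deterministic given ``aux``.

    All particles start at x = phi1 at time 0.  Per observation: propagate
    through the exact SDE transition over the elapsed gap using the step's
    column of ``particle_normals``, weight by the observation likelihood,
    record log(mean weight) as the predictive increment, then sort by state
    and systematic-resample with the step's single uniform.  The sort keeps
    the map from auxiliary variables to likelihood nearly continuous in the
    parameters, which is what makes the correlated pseudo-marginal scheme
    effective.
    """
    times = np.asarray(times, float)
    scores = np.asarray(scores)
    if times.size == 0:
        raise ValueError("empty observation sequence")
    if np.any(np.diff(times) < 0):
        raise ValueError("observation times must be sorted")
    n_obs = times.size
    if aux.n_steps != n_obs:
        raise ValueError(f"aux has {aux.n_steps} steps, need {n_obs}")

    phi = np.asarray(phi, float)
    uniforms = aux.resample_uniforms()
    x = np.full(aux.n_particles, phi[0])
    increments = np.empty(n_obs)
    min_ess = float(aux.n_particles)
    log_n = np.log(aux.n_particles)
    prev_t = 0.0
    for j in range(n_obs):
        dt = times[j] - prev_t
        mom = transition(x, dt, phi, spec)
        x = mom.mean + np.sqrt(mom.variance) * aux.particle_normals[:, j]
        logw = obs_model.loglik(scores[j], x)
        if not np.all(np.isfinite(logw)):
            raise FloatingPointError(
                f"non-finite particle weights at observation {j} for phi={phi}"
            )
        m = logw.max()
        w = np.exp(logw - m)
        sw = w.sum()
        increments[j] = m + np.log(sw) - log_n
        w /= sw
        min_ess = min(min_ess, 1.0 / np.sum(w * w))
        order = np.argsort(x, kind="stable")
        idx = _systematic_resample(w[order], uniforms[j])
        x = x[order][idx]
        prev_t = times[j]
    return ParticleFilterResult(float(increments.sum()), increments, x, min_ess)


# --------------------------------------------------------------------------
# population layer


@dataclass
class PopulationParams:
    """Population-level parameters.

    ``mu[j]`` is the population mean of random-effect slot j, or the shared
    value of a fixed-effect slot.  ``tau[j]`` is the population SD (only
    meaningful for random slots).  ``sigma_y`` is the shared observation SD.
    """

    mu: np.ndarray
    tau: np.ndarray
    sigma_y: float = 2.0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, float)
        self.tau = np.asarray(self.tau, float)
        if self.mu.shape != self.tau.shape:
            raise ValueError("mu and tau must have the same length")
        if np.any(self.tau < 0):
            raise ValueError("tau must be non-negative")

    def copy(self) -> "PopulationParams":
        return PopulationParams(self.mu.copy(), self.tau.copy(), self.sigma_y)


@dataclass
class Hyperpriors:
    """Semi-conjugate hyperpriors: mu_j ~ N(mu0, kappa0^2), tau_j^2 ~ InvGamma(a0, b0)."""

    mu0: np.ndarray
    kappa0: np.ndarray
    a0: np.ndarray
    b0: np.ndarray

    @classmethod
    def default(cls, n_slots: int) -> "Hyperpriors":
        return cls(
            mu0=np.zeros(n_slots),
            kappa0=np.full(n_slots, 5.0),
            a0=np.full(n_slots, 2.0),
            b0=np.full(n_slots, 1.0),
        )

    def __post_init__(self) -> None:
        for name in ("mu0", "kappa0", "a0", "b0"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        if np.any(self.kappa0 <= 0) or np.any(self.a0 <= 0) or np.any(self.b0 <= 0):
            raise ValueError("kappa0, a0, b0 must be positive")


def gibbs_update_population(
    phis: np.ndarray,
    spec: ModelSpec,
    hyper: Hyperpriors,
    pop: PopulationParams,
    rng: np.random.Generator,
) -> PopulationParams:
    """Exact semi-conjugate draw of (mu_j, tau_j) for every random slot.

    For slot j with M individual values phi_{1:M,j}: mu_j is drawn from its
    normal full conditional given tau_j, then tau_j^2 from its inverse-gamma
    full conditional given the fresh mu_j.  With M=0 both are drawn from
    the hyperprior.  Fixed slots are left untouched.
    """
    phis = np.atleast_2d(np.asarray(phis, float))
    M = phis.shape[0]
    new = pop.copy()
    for j in np.flatnonzero(spec.random_mask):
        if M == 0:
            mu_j = rng.normal(hyper.mu0[j], hyper.kappa0[j])
            tau2 = hyper.b0[j] / rng.gamma(hyper.a0[j])
        else:
            vals = phis[:, j]
            prec = 1.0 / hyper.kappa0[j] ** 2 + M / new.tau[j] ** 2
            mean = (hyper.mu0[j] / hyper.kappa0[j] ** 2 + vals.sum() / new.tau[j] ** 2) / prec
            mu_j = rng.normal(mean, np.sqrt(1.0 / prec))
            a = hyper.a0[j] + 0.5 * M
            b = hyper.b0[j] + 0.5 * np.sum((vals - mu_j) ** 2)
            tau2 = b / rng.gamma(a)
        new.mu[j] = mu_j
        new.tau[j] = np.sqrt(tau2)
    return new


def _random_effect_logprior(phi: np.ndarray, pop: PopulationParams, spec: ModelSpec) -> float:
    """Sum of N(mu_j, tau_j^2) log-densities over random slots only."""
    j = spec.random_mask
    z = (phi[j] - pop.mu[j]) / pop.tau[j]
    return float(np.sum(-0.5 * z * z - np.log(pop.tau[j])) - 0.5 * j.sum() * np.log(2 * np.pi))


# --------------------------------------------------------------------------
# MH kernels


@dataclass
class _IndividualState:
    """Mutable per-individual sampler state (parameters, aux block, cache)."""

    phi: np.ndarray
    aux: AuxiliaryVariables
    cached: ParticleFilterResult


def cpm_mh_individual_step(
    state: _IndividualState,
    pop: PopulationParams,
    spec: ModelSpec,
    times: np.ndarray,
    scores: np.ndarray,
    obs_model,
    proposal_scales: np.ndarray,
    rho: float,
    rng: np.random.Generator,
    loglik_fn=None,
) -> bool:
    """One correlated pseudo-marginal MH update of one individual's phi.

    Proposes a normal random-walk step on the random-effect slots together
    with a Crank-Nicolson refresh of the auxiliary block, and accepts with
    the pseudo-marginal ratio (estimated likelihood times random-effect
    prior).  ``loglik_fn(phi, aux)`` may replace the particle filter, e.g.
    with an exact likelihood for validation.  Mutates ``state`` in place on
    acceptance and returns the accept flag.
    """
    if loglik_fn is None:
        def loglik_fn(phi, aux):
            return particle_filter_loglik(times, scores, phi, spec, obs_model, aux)

    mask = spec.random_mask
    step = np.zeros_like(state.phi)
    step[mask] = proposal_scales[mask] * rng.standard_normal(mask.sum())
    phi_prop = state.phi + step
    fresh = draw_aux(rng, state.aux.n_particles, state.aux.n_steps)
    aux_prop = refresh_aux(state.aux, rho, fresh)

    res_prop = loglik_fn(phi_prop, aux_prop)
    log_alpha = (
        res_prop.total_loglik
        + _random_effect_logprior(phi_prop, pop, spec)
        - state.cached.total_loglik
        - _random_effect_logprior(state.phi, pop, spec)
    )
    if np.log(rng.uniform()) < log_alpha:
        state.phi = phi_prop
        state.aux = aux_prop
        state.cached = res_prop
        return True
    return False


# --------------------------------------------------------------------------
# full sampler


@dataclass
class SamplerConfig:
    """Knobs of the correlated pseudo-marginal MH-within-Gibbs sampler."""

    iterations: int = 2000
    burnin: int = 500
    n_particles: int = 100
    rho: float = 0.99
    proposal_scale: float = 0.25
    seed: int = 0
    estimate_sigma_y: bool = False
    sigma_y_proposal_scale: float = 0.1
    adapt: bool = True
    target_accept: float = 0.3
    individual_substeps: int = 1  # MH sweeps per individual per Gibbs iteration

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if not 0 <= self.burnin < self.iterations:
            raise ValueError("need 0 <= burnin < iterations")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")


@dataclass
class PosteriorSamples:
    """Post-burn-in MCMC draws plus pointwise log-likelihood increments."""

    spec: ModelSpec
    individual_ids: list
    phi: np.ndarray  # (n_draws, M, S)
    mu: np.ndarray  # (n_draws, S)
    tau: np.ndarray  # (n_draws, S)
    sigma_y: np.ndarray  # (n_draws,)
    increments: np.ndarray  # (n_draws, total observations)
    obs_slices: dict  # individual id -> slice into the increment axis
    accept_rate: dict  # individual id -> post-burn-in acceptance rate
    config: SamplerConfig = field(repr=False, default=None)
    obs_config: ObservationModelConfig = field(repr=False, default=None)

    @property
    def n_draws(self) -> int:
        return self.phi.shape[0]

    def phi_draws(self, individual_id) -> np.ndarray:
        """(n_draws, S) parameter draws for one individual."""
        m = self.individual_ids.index(individual_id)
        return self.phi[:, m, :]

    def increments_subset(self, individual_ids) -> np.ndarray:
        """Increment columns restricted to the given individuals."""
        cols = np.concatenate(
            [np.arange(self.obs_slices[i].start, self.obs_slices[i].stop) for i in individual_ids]
        )
        return self.increments[:, cols]

    def population_params(self, how: str = "mean") -> PopulationParams:
        """Point estimate of the population layer from the draws.

        ``how='mean'`` uses posterior means; ``how='map'`` uses marginal
        modes estimated by a Gaussian kernel density (the approximation used
        when freezing the population for dynamic individual updating).
        """
        if how == "mean":
            mu = self.mu.mean(axis=0)
            tau = self.tau.mean(axis=0)
            sy = float(self.sigma_y.mean())
        elif how == "map":
            mu = np.array([_marginal_mode(self.mu[:, j]) for j in range(self.mu.shape[1])])
            tau = np.array([_marginal_mode(self.tau[:, j]) for j in range(self.tau.shape[1])])
            sy = _marginal_mode(self.sigma_y)
        else:
            raise ValueError("how must be 'mean' or 'map'")
        return PopulationParams(mu, tau, sy)


def _marginal_mode(draws: np.ndarray) -> float:
    draws = np.asarray(draws, float)
    if np.ptp(draws) < 1e-12:
        return float(draws[0])
    from scipy.stats import gaussian_kde

    kde = gaussian_kde(draws)
    grid = np.linspace(draws.min(), draws.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def _moment_phi2(times, scores, obs_cfg) -> float:
    """Method-of-moments starting value for the log diffusion SD.

    Maps scores to the latent scale through the inverse link and takes the
    median squared increment per day.  Crude (observation noise inflates
    it) but it starts chains in the right order of magnitude, which
    matters: a pseudo-marginal chain started at a very high diffusion can
    wedge on a lucky likelihood overestimate.
    """
    lat = inverse_link(np.asarray(scores, float), obs_cfg)
    dt = np.diff(np.asarray(times, float))
    rate = np.median(np.diff(lat) ** 2 / np.maximum(dt, 1e-3))
    return 0.5 * float(np.log(np.clip(rate, 1e-4, 1e2)))


def _initial_phi(times, scores, pop, spec, obs_cfg) -> np.ndarray:
    phi = pop.mu.copy()
    phi[0] = inverse_link(float(scores[0]), obs_cfg)
    if spec.random_effects[1]:
        phi[1] = _moment_phi2(times, scores, obs_cfg)
    return phi


def _adapt_scale(log_scale: float, accepted: float, k: int, target: float) -> float:
    return log_scale + (2.0 / (k + 10) ** 0.6) * (accepted - target)


def run_mcmc(
    data: TrajectoryDataset,
    spec: ModelSpec,
    cfg: SamplerConfig,
    hyper: Hyperpriors | None = None,
    obs_cfg: ObservationModelConfig | None = None,
) -> PosteriorSamples:
    """Correlated pseudo-marginal MH-within-Gibbs over the full cohort.

    Per iteration: one CPM-MH update per individual, a joint pseudo-marginal
    MH update of any fixed-effect values (summed likelihood across the
    cohort), the exact Gibbs draw of the population means/SDs, and, when
    enabled, a pseudo-marginal MH update of the observation SD.  Proposal
    scales are adapted towards ``target_accept`` during burn-in only.
    Fully reproducible from ``cfg.seed``.
    """
    obs_cfg = obs_cfg or ObservationModelConfig()
    hyper = hyper or Hyperpriors.default(spec.n_slots)
    ids = data.individuals
    if not ids:
        raise ValueError("dataset is empty")
    short = [i for i in ids if data.n_obs_of(i) < 2]
    if short:
        raise ValueError(f"individuals with fewer than 2 observations: {short[:5]}")

    rng = np.random.default_rng(cfg.seed)
    obs_model = DiscretizedObservationModel(obs_cfg)
    S = spec.n_slots
    M = len(ids)
    mask = spec.random_mask

    # initial population: hyperprior means, unit SDs, baseline mean from data
    pop = PopulationParams(hyper.mu0.copy(), np.ones(S), obs_cfg.sigma_y)
    first_scores = [data.observations(i)[1][0] for i in ids]
    pop.mu[0] = float(np.mean([inverse_link(float(y), obs_cfg) for y in first_scores]))
    # diffusion slot (shared or random) starts at a data-informed value
    pop.mu[1] = float(
        np.median([_moment_phi2(*data.observations(i), obs_cfg) for i in ids])
    )

    obs_arrays = {i: data.observations(i) for i in ids}
    states: dict = {}
    for i in ids:
        t, y = obs_arrays[i]
        phi0 = _initial_phi(t, y, pop, spec, obs_cfg)
        aux = draw_aux(rng, cfg.n_particles, t.size)
        cached = particle_filter_loglik(t, y, phi0, spec, obs_model, aux)
        states[i] = _IndividualState(phi0, aux, cached)

    obs_slices = {}
    start = 0
    for i in ids:
        n = obs_arrays[i][0].size
        obs_slices[i] = slice(start, start + n)
        start += n
    n_obs_total = start

    n_keep = cfg.iterations - cfg.burnin
    out_phi = np.empty((n_keep, M, S))
    out_mu = np.empty((n_keep, S))
    out_tau = np.empty((n_keep, S))
    out_sigma = np.empty(n_keep)
    out_inc = np.empty((n_keep, n_obs_total))
    acc_post = {i: 0 for i in ids}

    log_scales = {i: np.log(cfg.proposal_scale) for i in ids}
    fixed_idx = np.flatnonzero(~mask)
    log_scale_fixed = np.log(cfg.proposal_scale)
    log_scale_sigma = np.log(cfg.sigma_y_proposal_scale)
    ess_warned = False

    for it in range(cfg.iterations):
        in_burnin = it < cfg.burnin
        # --- individual CPM-MH updates; proposal SD per slot follows the
        # current population SD (symmetric in phi given pop, so valid
        # within Metropolis-within-Gibbs), times an adapted multiplier
        base_scales = np.where(mask, np.maximum(pop.tau, 0.05), 0.0)
        for i in ids:
            t, y = obs_arrays[i]
            st = states[i]
            scales = np.exp(log_scales[i]) * base_scales
            acc_any = 0.0
            for _ in range(max(1, cfg.individual_substeps)):
                acc_any += cpm_mh_individual_step(
                    st, pop, spec, t, y, obs_model, scales, cfg.rho, rng
                )
            accepted = acc_any / max(1, cfg.individual_substeps)
            if in_burnin and cfg.adapt:
                log_scales[i] = _adapt_scale(log_scales[i], accepted, it, cfg.target_accept)
            elif not in_burnin:
                acc_post[i] += accepted
            if st.cached.min_ess < 0.1 * cfg.n_particles and not ess_warned:
                logger.warning(
                    "particle degeneracy: ESS < 10%% of particles for individual %r", i
                )
                ess_warned = True

        # --- shared fixed-effect update (pseudo-marginal on summed loglik)
        if fixed_idx.size:
            prop = pop.mu.copy()
            prop[fixed_idx] += np.exp(log_scale_fixed) * rng.standard_normal(fixed_idx.size)
            cur_total = sum(states[i].cached.total_loglik for i in ids)
            new_results = {}
            new_total = 0.0
            for i in ids:
                t, y = obs_arrays[i]
                phi_new = states[i].phi.copy()
                phi_new[fixed_idx] = prop[fixed_idx]
                r = particle_filter_loglik(t, y, phi_new, spec, obs_model, states[i].aux)
                new_results[i] = (phi_new, r)
                new_total += r.total_loglik
            z_new = (prop[fixed_idx] - hyper.mu0[fixed_idx]) / hyper.kappa0[fixed_idx]
            z_old = (pop.mu[fixed_idx] - hyper.mu0[fixed_idx]) / hyper.kappa0[fixed_idx]
            log_alpha = new_total - cur_total - 0.5 * float(z_new @ z_new - z_old @ z_old)
            accepted_f = np.log(rng.uniform()) < log_alpha
            if accepted_f:
                pop.mu[fixed_idx] = prop[fixed_idx]
                for i in ids:
                    states[i].phi, states[i].cached = new_results[i]
            if in_burnin and cfg.adapt:
                log_scale_fixed = _adapt_scale(log_scale_fixed, accepted_f, it, cfg.target_accept)

        # --- Gibbs update of the population normals
        phis = np.stack([states[i].phi for i in ids])
        pop = gibbs_update_population(phis, spec, hyper, pop, rng)

        # --- optional observation-SD update (prior: log sigma_y ~ N(0, 1))
        if cfg.estimate_sigma_y:
            log_sy = np.log(pop.sigma_y)
            log_sy_prop = log_sy + np.exp(log_scale_sigma) * rng.standard_normal()
            obs_model_prop = obs_model.with_sigma_y(float(np.exp(log_sy_prop)))
            cur_total = sum(states[i].cached.total_loglik for i in ids)
            new_results = {}
            new_total = 0.0
            for i in ids:
                t, y = obs_arrays[i]
                r = particle_filter_loglik(t, y, states[i].phi, spec, obs_model_prop, states[i].aux)
                new_results[i] = r
                new_total += r.total_loglik
            log_alpha = new_total - cur_total - 0.5 * (log_sy_prop**2 - log_sy**2)
            accepted_s = np.log(rng.uniform()) < log_alpha
            if accepted_s:
                pop.sigma_y = float(np.exp(log_sy_prop))
                obs_model = obs_model_prop
                for i in ids:
                    states[i].cached = new_results[i]
            if in_burnin and cfg.adapt:
                log_scale_sigma = _adapt_scale(log_scale_sigma, accepted_s, it, cfg.target_accept)

        # --- record
        if not in_burnin:
            k = it - cfg.burnin
            out_phi[k] = phis
            out_mu[k] = pop.mu
            out_tau[k] = pop.tau
            out_sigma[k] = pop.sigma_y
            for i in ids:
                out_inc[k, obs_slices[i]] = states[i].cached.increments

    accept_rate = {i: acc_post[i] / max(n_keep, 1) for i in ids}
    logger.info(
        "MCMC finished: %d kept draws, mean acceptance %.2f",
        n_keep,
        float(np.mean(list(accept_rate.values()))),
    )
    return PosteriorSamples(
        spec=spec,
        individual_ids=ids,
        phi=out_phi,
        mu=out_mu,
        tau=out_tau,
        sigma_y=out_sigma,
        increments=out_inc,
        obs_slices=obs_slices,
        accept_rate=accept_rate,
        config=cfg,
        obs_config=obs_cfg,
    )


def run_individual_mcmc(
    times: np.ndarray,
    scores: np.ndarray,
    pop: PopulationParams,
    spec: ModelSpec,
    cfg: SamplerConfig,
    obs_cfg: ObservationModelConfig | None = None,
    rng: np.random.Generator | None = None,
    loglik_fn=None,
) -> np.ndarray:
    """CPM-MH chain for a single individual with the population layer frozen.

    Used for dynamic updating: the population parameters act as a fixed
    prior (their posterior uncertainty is not propagated) and only the
    individual's phi is sampled.  Returns the (n_draws, S) post-burn-in phi
    draws.  Requires at least one observation; a single baseline observation
    is allowed (the chain then mostly reflects the population prior).
    """
    times = np.asarray(times, float)
    scores = np.asarray(scores)
    if times.size == 0:
        raise ValueError("empty observation prefix")
    obs_cfg = obs_cfg or ObservationModelConfig(sigma_y=pop.sigma_y)
    rng = rng or np.random.default_rng(cfg.seed)
    obs_model = DiscretizedObservationModel(obs_cfg).with_sigma_y(pop.sigma_y)

    phi0 = pop.mu.copy()
    phi0[0] = inverse_link(float(scores[0]), obs_cfg)
    aux = draw_aux(rng, cfg.n_particles, times.size)
    if loglik_fn is not None:
        cached = loglik_fn(phi0, aux)
    else:
        cached = particle_filter_loglik(times, scores, phi0, spec, obs_model, aux)
    state = _IndividualState(phi0, aux, cached)

    S = spec.n_slots
    n_keep = cfg.iterations - cfg.burnin
    out = np.empty((n_keep, S))
    log_scale = np.log(cfg.proposal_scale)
    base_scales = np.where(spec.random_mask, np.maximum(pop.tau, 0.05), 0.0)
    for it in range(cfg.iterations):
        scales = np.exp(log_scale) * base_scales
        accepted = cpm_mh_individual_step(
            state, pop, spec, times, scores, obs_model, scales, cfg.rho, rng, loglik_fn
        )
        if it < cfg.burnin:
            if cfg.adapt:
                log_scale = _adapt_scale(log_scale, accepted, it, cfg.target_accept)
        else:
            out[it - cfg.burnin] = state.phi
    return out


# --------------------------------------------------------------------------
# WAIC


def pointwise_loglik(
    samples: "PosteriorSamples",
    data: TrajectoryDataset,
    n_draws: int = 200,
    n_particles: int = 200,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Re-estimate per-observation log-likelihoods for thinned posterior draws.

    The increments stored during sampling carry the chain's own particle
    noise, which is serially correlated with the accept/reject history and
    inflates the WAIC variance penalty.  For model comparison the pointwise
    terms are therefore recomputed with fresh auxiliary variables and a
    larger particle count, one independent filter run per (draw,
    individual).  Returns a (thinned draws, total observations) matrix
    aligned with ``samples.obs_slices``.
    """
    rng = rng or np.random.default_rng(0)
    idx = np.unique(np.linspace(0, samples.n_draws - 1, n_draws).round().astype(int))
    obs_cfg = samples.obs_config or ObservationModelConfig()
    base_model = DiscretizedObservationModel(obs_cfg)
    n_obs_total = sum(data.n_obs_of(i) for i in samples.individual_ids)
    out = np.empty((idx.size, n_obs_total))
    for r, s in enumerate(idx):
        obs_model = base_model.with_sigma_y(float(samples.sigma_y[s]))
        for m, i in enumerate(samples.individual_ids):
            t, y = data.observations(i)
            aux = draw_aux(rng, n_particles, t.size)
            res = particle_filter_loglik(t, y, samples.phi[s, m], samples.spec, obs_model, aux)
            out[r, samples.obs_slices[i]] = res.increments
    return out


@dataclass(frozen=True)
class WaicResult:
    waic: float
    p_waic: float
    lppd: float


def waic(increments: np.ndarray) -> WaicResult:
    """WAIC on the deviance scale from pointwise posterior log-likelihoods.

    ``increments`` has shape (draws, observations).  lppd sums the log of
    the posterior-mean pointwise likelihood (log-sum-exp over draws); the
    effective number of parameters is the summed posterior variance of the
    pointwise log-likelihood; WAIC = -2 * (lppd - p_waic), lower is better.
    """
    ll = np.asarray(increments, float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws >= 2, observations) log-likelihood matrix")
    n_draws = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(n_draws)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return WaicResult(waic=-2.0 * (lppd - p_waic), p_waic=p_waic, lppd=lppd)
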