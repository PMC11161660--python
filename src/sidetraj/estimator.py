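"""Scikit-learn style estimator facade over the trajectory model.

``SDETrajectoryModel`` bundles the model variant, the observation model and
the sampler configuration behind ``fit`` / ``predict`` with
``get_params``/``set_params`` semantics, so it composes with scikit-learn
tooling (cloning, parameter grids).  ``X`` is the long-format observation
table (``individual_id``, ``time_days``, ``sidas_total``); there is no
``y`` — the model is generative over the trajectories themselves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .data import TrajectoryDataset, from_frame
from .inference import SamplerConfig, run_mcmc, waic
from .latent import ModelSpec
from .observation import ObservationModelConfig
from .prediction import (
    PredictiveSummary,
    covariate_association,
    simulate_predictive,
    summarize_paths,
    update_individual,
)

__all__ = ["SDETrajectoryModel"]


class SDETrajectoryModel(BaseEstimator):
    """Hierarchical continuous-time SDE model of ordinal score trajectories.

    Parameters
    ----------
    variant : int, default=2
        Model variant: 1 = Wiener with fixed diffusion, 2 = Wiener with
        random diffusion, 3 = OU with fixed drift rate, 4 = OU with all
        effects random.  Baseline is always a random effect.
    n_particles, rho, iterations, burnin, proposal_scale :
        Correlated pseudo-marginal sampler settings; ``rho`` is the
        Crank-Nicolson correlation of the auxiliary variables.
    sigma_y, link_scale, score_max :
        Observation-model settings (discretised normal SD on the score
        scale, logistic link steepness, top score).
    estimate_sigma_y : bool
        Sample sigma_y instead of fixing it.
    min_obs : int
        Inclusion rule — individuals with fewer observations are dropped.
    random_state : int
        Seed for the whole fit; fits are bit-reproducible.

    Attributes
    ----------
    posterior_ : PosteriorSamples
        All post-burn-in draws, including pointwise log-likelihoods.
    population_mean_ : PopulationParams
        Posterior-mean population parameters.
    waic_ : float
        WAIC (deviance scale) over all modelled observations.
    individual_ids_ : list
        Individuals retained after the inclusion rule.
    """

    def __init__(
        self,
        variant: int = 2,
        n_particles: int = 100,
        rho: float = 0.99,
        iterations: int = 1500,
        burnin: int = 500,
        proposal_scale: float = 0.25,
        sigma_y: float = 2.0,
        link_scale: float = 1.0,
        score_max: int = 50,
        estimate_sigma_y: bool = False,
        min_obs: int = 2,
        random_state: int = 0,
    ):
        self.variant = variant
        self.n_particles = n_particles
        self.rho = rho
        self.iterations = iterations
        self.burnin = burnin
        self.proposal_scale = proposal_scale
        self.sigma_y = sigma_y
        self.link_scale = link_scale
        self.score_max = score_max
        self.estimate_sigma_y = estimate_sigma_y
        self.min_obs = min_obs
        self.random_state = random_state

    # ---- configuration helpers -------------------------------------------------

    def _spec(self) -> ModelSpec:
        return ModelSpec.from_variant(self.variant)

    def _obs_cfg(self) -> ObservationModelConfig:
        return ObservationModelConfig(
            score_max=self.score_max, sigma_y=self.sigma_y, link_scale=self.link_scale
        )

    def _sampler_cfg(self) -> SamplerConfig:
        return SamplerConfig(
            iterations=self.iterations,
            burnin=self.burnin,
            n_particles=self.n_particles,
            rho=self.rho,
            proposal_scale=self.proposal_scale,
            seed=self.random_state,
            estimate_sigma_y=self.estimate_sigma_y,
        )

    def _as_dataset(self, X) -> TrajectoryDataset:
        if isinstance(X, TrajectoryDataset):
            return X
        if isinstance(X, pd.DataFrame):
            return from_frame(X, min_obs=self.min_obs, score_max=self.score_max)
        raise TypeError("X must be a long-format DataFrame or a TrajectoryDataset")

    # ---- estimator API ---------------------------------------------------------

    def fit(self, X, y=None) -> "SDETrajectoryModel":
        """Run the CPM-MH-within-Gibbs sampler on the observation table."""
        data = self._as_dataset(X)
        self.posterior_ = run_mcmc(data, self._spec(), self._sampler_cfg(), obs_cfg=self._obs_cfg())
        self.population_mean_ = self.posterior_.population_params("mean")
        self.waic_ = waic(self.posterior_.increments).waic
        self.individual_ids_ = list(self.posterior_.individual_ids)
        self._data_ = data
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "posterior_"):
            raise NotFittedError("this SDETrajectoryModel instance is not fitted yet")

    def predict(
        self,
        individual_id,
        horizon: int = 60,
        n_param_draws: int = 100,
        n_paths_per_draw: int = 20,
        threshold: int = 20,
        seed: int | None = None,
    ) -> PredictiveSummary:
        """60-day posterior predictive summary from an individual's last observation."""
        self._check_fitted()
        seed = self.random_state if seed is None else seed
        rng = np.random.default_rng(seed)
        paths = simulate_predictive(
            self._data_,
            self.posterior_,
            individual_id,
            horizon=horizon,
            n_param_draws=n_param_draws,
            n_paths_per_draw=n_paths_per_draw,
            rng=rng,
            n_particles=self.n_particles,
        )
        return summarize_paths(paths, threshold=threshold, seed=seed)

    def update_and_predict(
        self, times, scores, horizon: int = 60, seed: int | None = None
    ) -> PredictiveSummary:
        """Dynamic updating for a (possibly new) individual given a frozen population.

        Freezes the population layer at its marginal MAP estimates, refits
        only the individual against the observation prefix, and forecasts.
        """
        self._check_fitted()
        seed = self.random_state if seed is None else seed
        map_pop = self.posterior_.population_params("map")
        _, summary = update_individual(
            map_pop,
            np.asarray(times, float),
            np.asarray(scores),
            self._spec(),
            self._sampler_cfg(),
            obs_cfg=self._obs_cfg(),
            horizon=horizon,
            rng=np.random.default_rng(seed),
        )
        return summary

    def associate(self, covariates: pd.DataFrame) -> pd.DataFrame:
        """Posterior association of baseline covariates with the diffusion parameter."""
        self._check_fitted()
        return covariate_association(self.posterior_, covariates)

    def score(self, X=None, y=None) -> float:
        """Model score as -WAIC/2 (higher is better), for sklearn tooling."""
        self._check_fitted()
        return -0.5 * self.waic_
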