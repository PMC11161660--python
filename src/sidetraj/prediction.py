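"""Posterior predictive forecasting and its clinical summaries.

Given posterior draws for an individual, future score trajectories are
simulated on a daily grid over a 60-day horizon: a posterior parameter draw
is selected, the current latent state is drawn from the particle filtering
distribution at the last observation, the latent SDE is stepped forward
exactly day by day, and an integer score is sampled each day through the
observation model.  The resulting path matrix is summarised by

* daily median and 68% / 95% equal-tailed credible intervals (ETI),
* IHIP — the probability that the score exceeds 20 on *any* day of the
  horizon (integrated high-ideation probability),
* FUT — the first day on which the 95% ETI range exceeds half the score
  range (> 25), a recommended follow-up time; censored at the horizon,
* V — the expected 95% ETI range of the score at the horizon, computed per
  posterior parameter draw and averaged, with an 80% HDI across draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .data import TrajectoryDataset
from .inference import (
    PopulationParams,
    PosteriorSamples,
    SamplerConfig,
    draw_aux,
    particle_filter_loglik,
    run_individual_mcmc,
)
from .latent import ModelSpec, simulate_latent_path, transition
from .observation import (
    DiscretizedObservationModel,
    ObservationModelConfig,
    inverse_link,
    link_mean,
)

__all__ = [
    "PredictiveSummary",
    "eti",
    "hdi",
    "compute_ihip",
    "compute_fut",
    "compute_v",
    "simulate_paths",
    "simulate_predictive",
    "summarize_paths",
    "update_individual",
    "covariate_association",
    "prior_predictive_baseline",
    "diffusion_score_range",
]

HIGH_IDEATION_THRESHOLD = 20
FUT_RANGE_THRESHOLD = 25.0  # half the 0..50 SIDAS range


def eti(draws, level: float) -> tuple[float, float]:
    """Equal-tailed credible interval: ((1-level)/2, 1-(1-level)/2) quantiles."""
    draws = np.asarray(draws, float)
    if draws.size == 0:
        raise ValueError("eti of an empty sample")
    if not 0.0 < level <= 1.0:
        raise ValueError("level must lie in (0, 1]")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [a, 1.0 - a])
    return float(lo), float(hi)


def hdi(draws, level: float) -> tuple[float, float]:
    """Highest-density interval via the sorted shortest-window algorithm."""
    draws = np.sort(np.asarray(draws, float))
    n = draws.size
    if n < 2:
        raise ValueError("hdi needs at least 2 draws")
    if not 0.0 < level <= 1.0:
        raise ValueError("level must lie in (0, 1]")
    k = min(n, max(2, int(np.ceil(level * n))))
    widths = draws[k - 1 :] - draws[: n - k + 1]
    i = int(np.argmin(widths))
    return float(draws[i]), float(draws[i + k - 1])


def compute_ihip(daily_draws: np.ndarray, threshold: int = HIGH_IDEATION_THRESHOLD) -> float:
    """Fraction of paths whose maximum daily score strictly exceeds ``threshold``."""
    paths = np.asarray(daily_draws)
    if paths.size == 0:
        raise ValueError("empty path matrix")
    paths = paths.reshape(-1, paths.shape[-1])
    return float(np.mean(paths.max(axis=1) > threshold))


def compute_fut(daily_eti95_ranges, threshold: float = FUT_RANGE_THRESHOLD) -> tuple[int, bool]:
    """First day (1-based) whose 95% ETI range exceeds ``threshold``.

    Returns ``(day, censored)``; if no day crosses, the horizon length is
    returned with ``censored=True``.
    """
    ranges = np.asarray(daily_eti95_ranges, float)
    over = np.flatnonzero(ranges > threshold)
    if over.size == 0:
        return int(ranges.size), True
    return int(over[0] + 1), False


def compute_v(day_horizon_draws: np.ndarray, level: float = 0.95, hdi_level: float = 0.80):
    """Expected horizon-day ETI range across posterior parameter draws.

    ``day_horizon_draws`` has shape (parameter draws, paths per draw): the
    95% ETI range of the horizon-day score is computed within each parameter
    draw, then averaged (V) and summarised by an 80% HDI.
    """
    grouped = np.atleast_2d(np.asarray(day_horizon_draws, float))
    if grouped.shape[0] < 2:
        raise ValueError("compute_v needs >= 2 parameter-draw groups")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(grouped, [a, 1.0 - a], axis=1)
    ranges = hi - lo
    return float(ranges.mean()), hdi(ranges, hdi_level), ranges


@dataclass
class PredictiveSummary:
    """Daily forecast bands plus the IHIP / V / FUT severity summaries."""

    horizon_days: int
    daily_median: np.ndarray
    daily_eti68_lo: np.ndarray
    daily_eti68_hi: np.ndarray
    daily_eti95_lo: np.ndarray
    daily_eti95_hi: np.ndarray
    ihip: float
    fut_days: int
    fut_censored: bool
    v: float
    v_hdi80: tuple[float, float]
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "daily_median",
            "daily_eti68_lo",
            "daily_eti68_hi",
            "daily_eti95_lo",
            "daily_eti95_hi",
        ):
            setattr(self, name, np.asarray(getattr(self, name), float))
        if not 0.0 <= self.ihip <= 1.0:
            raise ValueError("ihip must lie in [0, 1]")
        if self.fut_days < 1:
            raise ValueError("fut_days must be >= 1")

    def to_json(self) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        d["v_hdi80"] = list(d["v_hdi80"])
        return json.dumps(d)


def summarize_paths(
    score_paths: np.ndarray,
    threshold: int = HIGH_IDEATION_THRESHOLD,
    seed: int | None = None,
) -> PredictiveSummary:
    """Summarise a (param draws, paths, horizon) score-path array."""
    paths = np.asarray(score_paths, float)
    if paths.ndim != 3:
        raise ValueError("score_paths must have shape (param draws, paths, horizon)")
    g, p, horizon = paths.shape
    flat = paths.reshape(g * p, horizon)
    med = np.median(flat, axis=0)
    e68 = np.quantile(flat, [0.16, 0.84], axis=0)
    e95 = np.quantile(flat, [0.025, 0.975], axis=0)
    fut_days, censored = compute_fut(e95[1] - e95[0])
    v, v_hdi80, _ = compute_v(paths[:, :, -1])
    return PredictiveSummary(
        horizon_days=horizon,
        daily_median=med,
        daily_eti68_lo=e68[0],
        daily_eti68_hi=e68[1],
        daily_eti95_lo=e95[0],
        daily_eti95_hi=e95[1],
        ihip=compute_ihip(flat, threshold),
        fut_days=fut_days,
        fut_censored=censored,
        v=v,
        v_hdi80=v_hdi80,
        seed=seed,
    )


def simulate_paths(
    phi_draws: np.ndarray,
    sigma_y_draws: np.ndarray,
    times: np.ndarray,
    scores: np.ndarray,
    spec: ModelSpec,
    obs_cfg: ObservationModelConfig,
    horizon: int,
    n_paths_per_draw: int,
    rng: np.random.Generator,
    n_particles: int = 100,
) -> np.ndarray:
    """Simulate daily future scores from the last observation.

    For each parameter draw the current latent state is sampled from the
    particle filtering distribution at the last observation (not a point
    estimate), then the latent SDE is stepped exactly one day at a time and
    an integer score drawn each day.  Returns an int array of shape
    (n draws, n_paths_per_draw, horizon).
    """
    phi_draws = np.atleast_2d(np.asarray(phi_draws, float))
    sigma_y_draws = np.broadcast_to(np.asarray(sigma_y_draws, float), (phi_draws.shape[0],))
    times = np.asarray(times, float)
    scores = np.asarray(scores)
    if n_paths_per_draw < 1:
        raise ValueError("n_paths_per_draw must be >= 1")
    g = phi_draws.shape[0]
    out = np.empty((g, n_paths_per_draw, horizon), dtype=np.int64)
    base_model = DiscretizedObservationModel(obs_cfg)
    for s in range(g):
        obs_model = base_model.with_sigma_y(float(sigma_y_draws[s]))
        aux = draw_aux(rng, n_particles, times.size)
        res = particle_filter_loglik(times, scores, phi_draws[s], spec, obs_model, aux)
        x = rng.choice(res.final_particles, size=n_paths_per_draw, replace=True)
        for d in range(horizon):
            mom = transition(x, 1.0, phi_draws[s], spec)
            x = mom.mean + np.sqrt(mom.variance) * rng.standard_normal(n_paths_per_draw)
            out[s, :, d] = obs_model.sample(x, rng.uniform(size=n_paths_per_draw))
    return out


def simulate_predictive(
    data: TrajectoryDataset,
    samples: PosteriorSamples,
    individual_id,
    horizon: int = 60,
    n_param_draws: int = 100,
    n_paths_per_draw: int = 20,
    rng: np.random.Generator | None = None,
    last_obs_index: int | None = None,
    n_particles: int = 100,
) -> np.ndarray:
    """Posterior predictive score paths for one fitted individual.

    Parameter draws are an evenly spaced thinning of the stored posterior.
    ``last_obs_index`` restricts the conditioning history to the first
    ``last_obs_index + 1`` observations (default: all).
    """
    rng = rng or np.random.default_rng(0)
    if individual_id not in samples.individual_ids:
        raise KeyError(f"individual {individual_id!r} not present in posterior samples")
    t, y = data.observations(individual_id)
    if last_obs_index is not None:
        t, y = t[: last_obs_index + 1], y[: last_obs_index + 1]
    phi_all = samples.phi_draws(individual_id)
    idx = np.unique(np.linspace(0, samples.n_draws - 1, n_param_draws).round().astype(int))
    return simulate_paths(
        phi_all[idx],
        samples.sigma_y[idx],
        t,
        y,
        samples.spec,
        samples.obs_config or ObservationModelConfig(),
        horizon,
        n_paths_per_draw,
        rng,
        n_particles=n_particles,
    )


def update_individual(
    map_pop: PopulationParams,
    times: np.ndarray,
    scores: np.ndarray,
    spec: ModelSpec,
    cfg: SamplerConfig,
    obs_cfg: ObservationModelConfig | None = None,
    horizon: int = 60,
    n_param_draws: int = 100,
    n_paths_per_draw: int = 20,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, PredictiveSummary]:
    """Dynamic per-individual updating against a frozen population prior.

    Runs the single-individual CPM-MH chain with the population layer fixed
    at point estimates (typically the population MAP), then produces the
    60-day predictive summary from the last observation of the prefix.
    Repeating this as observations accrue reproduces the clinical updating
    loop in which predictions tighten with each new data point.
    """
    times = np.asarray(times, float)
    scores = np.asarray(scores)
    if times.size == 0:
        raise ValueError("empty observation prefix")
    obs_cfg = obs_cfg or ObservationModelConfig(sigma_y=map_pop.sigma_y)
    rng = rng or np.random.default_rng(cfg.seed)
    phi_draws = run_individual_mcmc(times, scores, map_pop, spec, cfg, obs_cfg, rng)
    idx = np.unique(np.linspace(0, phi_draws.shape[0] - 1, n_param_draws).round().astype(int))
    paths = simulate_paths(
        phi_draws[idx],
        np.full(idx.size, map_pop.sigma_y),
        times,
        scores,
        spec,
        obs_cfg,
        horizon,
        n_paths_per_draw,
        rng,
        n_particles=cfg.n_particles,
    )
    return phi_draws, summarize_paths(paths, seed=cfg.seed)


def covariate_association(
    samples: PosteriorSamples,
    covariates: pd.DataFrame,
    slot: int = 1,
    level: float = 0.95,
) -> pd.DataFrame:
    """Association between baseline covariates and an individual parameter.

    For each posterior draw the per-individual values of parameter ``slot``
    (default: the diffusion parameter phi2) are compared with the covariate
    across individuals: a Pearson correlation for continuous covariates, a
    difference of group means for binary (0/1) covariates.  The per-draw
    statistics are summarised by their mean and 95% ETI, so the reported
    uncertainty is posterior uncertainty in the individual parameters.
    """
    ids = [i for i in samples.individual_ids if i in covariates.index]
    if len(ids) < 3:
        raise ValueError("need covariate values for at least 3 fitted individuals")
    order = [samples.individual_ids.index(i) for i in ids]
    phi = samples.phi[:, order, slot]  # (draws, individuals)
    rows = []
    for col in covariates.columns:
        v = covariates.loc[ids, col].to_numpy(float)
        if np.ptp(v) == 0:
            raise ValueError(f"covariate {col!r} is constant; association undefined")
        binary = set(np.unique(v)) <= {0.0, 1.0}
        if binary:
            stat = phi[:, v == 1].mean(axis=1) - phi[:, v == 0].mean(axis=1)
            kind = "binary-difference"
        else:
            vc = v - v.mean()
            pc = phi - phi.mean(axis=1, keepdims=True)
            stat = (pc @ vc) / np.sqrt((pc**2).sum(axis=1) * (vc**2).sum())
            kind = "correlation"
        lo, hi = eti(stat, level)
        rows.append({"covariate": col, "kind": kind, "mean": float(stat.mean()), "eti_lo": lo, "eti_hi": hi})
    return pd.DataFrame(rows).set_index("covariate")


def prior_predictive_baseline(
    pop: PopulationParams,
    spec: ModelSpec,
    obs_cfg: ObservationModelConfig,
    n_draws: int,
    rng: np.random.Generator,
) -> dict:
    """Prior predictive draws of the baseline score and diffusion parameter.

    Draws phi from the population normals (fixed slots copied), maps phi1
    through the observation model to a predicted baseline score, and
    summarises both margins by median and 95% HDI.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    mask = spec.random_mask
    phi = np.tile(pop.mu, (n_draws, 1))
    phi[:, mask] = phi[:, mask] + pop.tau[mask] * rng.standard_normal((n_draws, mask.sum()))
    obs_model = DiscretizedObservationModel(obs_cfg).with_sigma_y(pop.sigma_y)
    y0 = np.asarray(obs_model.sample(phi[:, 0], rng.uniform(size=n_draws)))
    out = {"y0_draws": y0, "phi2_draws": phi[:, 1]}
    out["y0_median"] = float(np.median(y0))
    out["y0_hdi95"] = hdi(y0, 0.95)
    out["phi2_median"] = float(np.median(phi[:, 1]))
    out["phi2_hdi95"] = hdi(phi[:, 1], 0.95)
    return out


def diffusion_score_range(
    start_score: float,
    phi2: float,
    days: float = 7.0,
    level: float = 0.68,
    n_paths: int = 20000,
    rng: np.random.Generator | None = None,
    obs_cfg: ObservationModelConfig | None = None,
) -> tuple[int, int]:
    """Score range a Wiener trajectory diffuses to after ``days`` days.

    Simulates latent random-walk paths from the latent state matching
    ``start_score``, maps them through the logistic link onto the score
    scale, and returns the ETI at ``level`` rounded to integer scores.  With
    the defaults this is the one-sigma (68%) range of the trajectory itself,
    excluding observation noise.
    """
    obs_cfg = obs_cfg or ObservationModelConfig()
    rng = rng or np.random.default_rng(0)
    x0 = float(inverse_link(start_score, obs_cfg))
    z = rng.standard_normal(n_paths)
    x_day = x0 + np.exp(phi2) * np.sqrt(days) * z
    scores = link_mean(x_day, obs_cfg)
    lo, hi = eti(scores, level)
    return int(round(lo)), int(round(hi))
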