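"""Ordinal observation model mapping latent states to SIDAS scores.

The summed SIDAS score is an integer on 0..50 (five items, each 0-10).  A
latent state x is mapped to the score scale by a scaled logistic link,

    m(x) = score_max * logistic(link_scale * x),

and the observed score is a *discretised normal* around m(x) with SD
``sigma_y``:  interior bins get ``Phi((k+0.5-m)/s) - Phi((k-0.5-m)/s)`` and
the two boundary bins absorb the tails, so the pmf is exact, sums to one,
and every score has positive mass for every finite latent state.

A continuous linear-Gaussian observation law (identity link, normal
density) is also provided; it turns the state-space model into one with a
closed-form Kalman likelihood and exists purely as an oracle hook for
validating the particle filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_ndtr, logit, ndtr, ndtri

__all__ = [
    "ObservationModelConfig",
    "DiscretizedObservationModel",
    "GaussianObservationModel",
    "link_mean",
    "inverse_link",
    "discretized_normal_pmf",
    "observation_loglik",
    "sample_observation",
]

# log-probabilities are floored here so that the likelihood stays finite
# even when the interval probability underflows double precision
_LOG_FLOOR = np.log(np.finfo(float).tiny)


@dataclass(frozen=True)
class ObservationModelConfig:
    """Configuration of the discretised-normal ordinal observation model.

    score_max: top of the score range (50 for the summed SIDAS).
    sigma_y: SD of the discretised normal on the score scale.
    link_scale: steepness of the logistic link (1 = canonical).
    """

    score_max: int = 50
    sigma_y: float = 2.0
    link_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.score_max < 1:
            raise ValueError("score_max must be >= 1")
        if self.sigma_y <= 0:
            raise ValueError("sigma_y must be positive")
        if self.link_scale <= 0:
            raise ValueError("link_scale must be positive")


def link_mean(x, cfg: ObservationModelConfig = ObservationModelConfig()):
    """Latent state -> expected score in (0, score_max); strictly increasing."""
    return cfg.score_max * expit(cfg.link_scale * np.asarray(x, dtype=float))


def inverse_link(y, cfg: ObservationModelConfig = ObservationModelConfig()):
    """Score -> latent state; exact inverse of :func:`link_mean`.

    Scores of exactly 0 or score_max sit at the link's asymptotes, so they
    are offset 0.5 score units inward before inversion.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > cfg.score_max):
        raise ValueError(f"score must lie in [0, {cfg.score_max}]")
    y = np.where(y == 0, 0.5, y)
    y = np.where(y == cfg.score_max, cfg.score_max - 0.5, y)
    return logit(y / cfg.score_max) / cfg.link_scale


def _log_interval_prob(z_lo, z_hi):
    """log(Phi(z_hi) - Phi(z_lo)) for z_lo < z_hi, stable in both tails."""
    z_lo = np.asarray(z_lo, dtype=float)
    z_hi = np.asarray(z_hi, dtype=float)
    # reflect right-tail intervals into the left tail where log_ndtr is stable
    flip = z_lo + z_hi > 0
    a = np.where(flip, -z_hi, z_lo)
    b = np.where(flip, -z_lo, z_hi)
    lb = log_ndtr(b)
    la = log_ndtr(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = lb + np.log1p(-np.exp(la - lb))
    return np.maximum(np.nan_to_num(out, nan=_LOG_FLOOR, neginf=_LOG_FLOOR), _LOG_FLOOR)


def discretized_normal_pmf(mu: float, sigma_y: float, score_max: int) -> np.ndarray:
    """Probability vector over {0..score_max} for a discretised N(mu, sigma_y^2).

    Interior bins integrate the density over (k-0.5, k+0.5]; the boundary
    bins absorb the respective tails so the vector sums to one exactly.
    """
    if sigma_y <= 0:
        raise ValueError("sigma_y must be positive")
    k = np.arange(score_max + 1)
    upper = ndtr((k + 0.5 - mu) / sigma_y)
    lower = ndtr((k - 0.5 - mu) / sigma_y)
    p = upper - lower
    p[0] = upper[0]
    p[-1] = 1.0 - lower[-1]
    return p


def observation_loglik(y: int, x, cfg: ObservationModelConfig = ObservationModelConfig()):
    """log p(score = y | latent x) under the discretised-normal model.

    Vectorised over ``x``; finite for every finite x because boundary bins
    absorb the tails (numerically floored at the smallest positive double).
    """
    y = int(y)
    if y < 0 or y > cfg.score_max:
        raise ValueError(f"score {y} outside 0..{cfg.score_max}")
    mu = link_mean(x, cfg)
    s = cfg.sigma_y
    if y == 0:
        return np.maximum(log_ndtr((0.5 - mu) / s), _LOG_FLOOR)
    if y == cfg.score_max:
        return np.maximum(log_ndtr(-(cfg.score_max - 0.5 - mu) / s), _LOG_FLOOR)
    return _log_interval_prob((y - 0.5 - mu) / s, (y + 0.5 - mu) / s)


def sample_observation(x, cfg: ObservationModelConfig, u):
    """Inverse-CDF draw of the score given latent ``x`` and uniform ``u``.

    Returns the smallest k whose cumulative pmf exceeds u, which for the
    discretised normal is round-half-up of ``m(x) + sigma_y * ndtri(u)``
    clipped into the score range.  Vectorised; deterministic given u.
    """
    mu = link_mean(x, cfg)
    with np.errstate(divide="ignore"):
        z = ndtri(np.asarray(u, dtype=float))
    raw = np.floor(mu + cfg.sigma_y * z + 0.5)
    k = np.clip(raw, 0, cfg.score_max)
    if np.ndim(k) == 0:
        return int(k)
    return k.astype(np.int64)


class DiscretizedObservationModel:
    """Object facade over the discretised-normal score model.

    The particle filter and simulators only touch this interface
    (``loglik``, ``sample``), so alternative observation laws can be slotted
    in without touching the inference code.
    """

    def __init__(self, cfg: ObservationModelConfig = ObservationModelConfig()):
        self.cfg = cfg

    @property
    def sigma_y(self) -> float:
        return self.cfg.sigma_y

    def with_sigma_y(self, sigma_y: float) -> "DiscretizedObservationModel":
        return DiscretizedObservationModel(
            ObservationModelConfig(self.cfg.score_max, sigma_y, self.cfg.link_scale)
        )

    def loglik(self, y, x):
        return observation_loglik(y, x, self.cfg)

    def sample(self, x, u):
        return sample_observation(x, self.cfg, u)


class GaussianObservationModel:
    """Linear-Gaussian observation law: y | x ~ N(x, sigma_y^2), identity link.

    Test-mode observation model that makes the whole state-space model
    linear-Gaussian, so the particle-filter likelihood can be checked
    against the exact Kalman-filter likelihood.
    """

    def __init__(self, sigma_y: float):
        if sigma_y <= 0:
            raise ValueError("sigma_y must be positive")
        self.sigma_y = float(sigma_y)

    def with_sigma_y(self, sigma_y: float) -> "GaussianObservationModel":
        return GaussianObservationModel(sigma_y)

    def loglik(self, y, x):
        x = np.asarray(x, dtype=float)
        z = (float(y) - x) / self.sigma_y
        return -0.5 * z * z - np.log(self.sigma_y) - 0.5 * np.log(2.0 * np.pi)

    def sample(self, x, u):
        with np.errstate(divide="ignore"):
            return np.asarray(x, dtype=float) + self.sigma_y * ndtri(np.asarray(u, float))
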