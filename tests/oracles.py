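"""Independent reference implementations used only to validate the package.

These deliberately avoid the package's particle filter and samplers:
quadrature and dense-grid filtering give (near-)exact likelihoods for tiny
problems, and the scalar Kalman filter gives the exact likelihood of the
linear-Gaussian test mode.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from sidetraj.latent import ModelSpec, transition
from sidetraj.observation import observation_loglik


def quadrature_loglik_two_obs(times, scores, phi, spec, obs_cfg, n_nodes=201):
    """Exact log-likelihood of a 2-observation series by Gauss-Hermite quadrature.

    First observation must be at t=0 (latent state fixed at phi1); the
    second integrates over the Gaussian transition.
    """
    assert len(times) == 2 and times[0] == 0.0
    ll0 = float(observation_loglik(int(scores[0]), phi[0], obs_cfg))
    mom = transition(np.array([phi[0]]), times[1] - times[0], np.asarray(phi), spec)
    mean, sd = float(mom.mean[0]), float(np.sqrt(mom.variance[0]))
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    x = mean + sd * nodes
    ll1_vals = observation_loglik(int(scores[1]), x, obs_cfg)
    w = weights / np.sqrt(2.0 * np.pi)
    ll1 = float(np.log(np.sum(w * np.exp(ll1_vals))))
    return ll0 + ll1


def _gauss_pdf(z, sd):
    return np.exp(-0.5 * (z / sd) ** 2) / (sd * np.sqrt(2.0 * np.pi))


def grid_filter_loglik(times, scores, phi, spec, obs_cfg, n_grid=400, pad=6.0):
    """Near-exact log-likelihood by dense-grid (HMM-style) filtering.

    Discretises the latent space on a fixed grid wide enough to cover the
    diffusion over the whole series and propagates the filtering density
    with exact Gaussian transition kernels.
    """
    times = np.asarray(times, float)
    phi = np.asarray(phi, float)
    total_sd = max(1e-3, np.sqrt(np.exp(2 * phi[1]) * max(times[-1], 1.0)))
    centre = phi[0]
    half = pad * total_sd + 1.0
    grid = np.linspace(centre - half, centre + half, n_grid)
    dx = grid[1] - grid[0]
    obs_ll = {int(y): observation_loglik(int(y), grid, obs_cfg) for y in set(int(v) for v in scores)}

    dens = None  # filtering density on grid
    prev_t = 0.0
    total = 0.0
    for j, (t, y) in enumerate(zip(times, scores)):
        dt = t - prev_t
        if j == 0 and dt == 0.0:
            pred = None  # point mass at phi1
        elif dens is None:
            mom = transition(np.array([phi[0]]), dt, phi, spec)
            pred = _gauss_pdf(grid - float(mom.mean[0]), float(np.sqrt(mom.variance[0])))
        else:
            mom = transition(grid, dt, phi, spec)
            sd = np.sqrt(mom.variance)
            kernel = _gauss_pdf(grid[:, None] - mom.mean[None, :], sd[None, :])
            pred = kernel @ dens * dx
        if pred is None:
            total += float(observation_loglik(int(y), phi[0], obs_cfg))
        else:
            post = pred * np.exp(obs_ll[int(y)])
            marg = np.trapezoid(post, grid)
            total += np.log(marg)
            dens = post / marg
        prev_t = t
    return float(total)


def kalman_loglik(times, scores, phi, spec: ModelSpec, sigma_y: float):
    """Exact likelihood for the linear-Gaussian mode: y_t = x_t + N(0, sigma_y^2).

    Scalar Kalman filter over the exact SDE transitions, initial state a
    point mass at phi1 at time 0.
    """
    times = np.asarray(times, float)
    phi = np.asarray(phi, float)
    m, P = phi[0], 0.0
    prev_t = 0.0
    total = 0.0
    for t, y in zip(times, scores):
        dt = t - prev_t
        if spec.model_type == "wiener":
            m_pred = m
            P_pred = P + np.exp(2 * phi[1]) * dt
        else:
            theta = np.exp(phi[2])
            a = np.exp(-theta * dt)
            m_pred = phi[3] + (m - phi[3]) * a
            P_pred = P * a * a + np.exp(2 * phi[1]) * (-np.expm1(-2 * theta * dt)) / (2 * theta)
        S = P_pred + sigma_y**2
        total += norm.logpdf(float(y), m_pred, np.sqrt(S))
        K = P_pred / S
        m = m_pred + K * (float(y) - m_pred)
        P = (1 - K) * P_pred
        prev_t = t
    return float(total)
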