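"""Credible intervals, forecast simulation and the IHIP / V / FUT summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri

from sidetraj import (
    ModelSpec,
    ObservationModelConfig,
    PopulationParams,
    PosteriorSamples,
    SamplerConfig,
    compute_fut,
    compute_ihip,
    compute_v,
    covariate_association,
    eti,
    hdi,
    inverse_link,
    prior_predictive_baseline,
    simulate_paths,
    summarize_paths,
    update_individual,
)


class TestEti:
    def test_level_one_is_min_max(self, rng):
        x = rng.normal(size=100)
        assert eti(x, 1.0) == (x.min(), x.max())

    def test_large_sample_normal_quantiles(self, rng):
        x = rng.standard_normal(1_000_000)
        lo, hi = eti(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.01)
        assert hi == pytest.approx(1.96, abs=0.01)

    def test_constant_draws_zero_width(self):
        lo, hi = eti(np.full(10, 3.3), 0.5)
        assert lo == hi == 3.3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            eti([], 0.9)


class TestHdi:
    def test_symmetric_unimodal_close_to_eti(self, rng):
        x = rng.standard_normal(1_000_000)
        e = eti(x, 0.8)
        h = hdi(x, 0.8)
        assert (h[1] - h[0]) == pytest.approx(e[1] - e[0], rel=0.02)

    def test_exponential_hdi_starts_at_zero(self, rng):
        x = rng.exponential(1.0, size=200_000)
        lo, hi = hdi(x, 0.8)
        assert lo < 0.01
        assert hi == pytest.approx(-np.log(0.2), rel=0.05)

    def test_constant_draws_zero_width(self):
        lo, hi = hdi(np.full(5, 1.0), 0.9)
        assert lo == hi == 1.0

    def test_shorter_than_any_other_window(self, rng):
        x = rng.normal(size=5001)
        lo, hi = hdi(x, 0.6)
        xs = np.sort(x)
        k = int(np.ceil(0.6 * x.size))
        assert hi - lo == pytest.approx(np.min(xs[k - 1 :] - xs[: x.size - k + 1]))


class TestIhip:
    def test_counting_definition(self):
        assert compute_ihip(np.zeros((4, 10))) == 0.0
        assert compute_ihip(np.full((4, 10), 30)) == 1.0
        paths = np.zeros((4, 10))
        paths[2, 7] = 21  # one path exceeds once
        assert compute_ihip(paths) == 0.25

    def test_strictly_greater_than_threshold(self):
        paths = np.zeros((2, 5))
        paths[0, :] = 20  # touching 20 never counts
        assert compute_ihip(paths) == 0.0

    def test_monotone_in_horizon_and_threshold(self, rng):
        paths = rng.integers(0, 51, size=(200, 60))
        ih_30 = compute_ihip(paths[:, :30])
        ih_60 = compute_ihip(paths)
        assert ih_60 >= ih_30
        assert compute_ihip(paths, threshold=10) >= compute_ihip(paths, threshold=30)


class TestFut:
    def test_first_crossing(self):
        assert compute_fut([10, 20, 26, 30, 24]) == (3, False)

    def test_censored_at_horizon(self):
        day, censored = compute_fut(np.full(60, 25.0))  # threshold is strict
        assert (day, censored) == (60, True)

    def test_monotone_in_diffusion(self, rng, wiener_spec):
        """Larger diffusion loses information faster: FUT is non-increasing."""
        obs_cfg = ObservationModelConfig()
        t = np.array([0.0])
        y = np.array([10])
        futs = []
        for phi2 in (-2.0, -0.5):
            paths = simulate_paths(
                np.array([[inverse_link(10.0, obs_cfg), phi2]]), np.array([2.0]),
                t, y, wiener_spec, obs_cfg, horizon=60, n_paths_per_draw=800,
                rng=np.random.default_rng(5),
            )
            flat = paths.reshape(-1, 60)
            lo, hi = np.quantile(flat, [0.025, 0.975], axis=0)
            futs.append(compute_fut(hi - lo)[0])
        assert futs[1] <= futs[0]


class TestComputeV:
    def test_degenerate_dynamics_zero(self):
        v, v_hdi, _ = compute_v(np.full((5, 40), 7.0))
        assert v == 0.0
        assert v_hdi == (0.0, 0.0)

    def test_identical_groups_zero_width_hdi(self, rng):
        row = rng.integers(0, 51, size=40)
        v, v_hdi, ranges = compute_v(np.tile(row, (6, 1)))
        assert np.allclose(ranges, ranges[0])
        assert v_hdi == (v, v)

    def test_streamed_equals_batch(self, rng):
        grouped = rng.integers(0, 51, size=(50, 30)).astype(float)
        v, _, ranges = compute_v(grouped)
        manual = np.array(
            [np.quantile(g, 0.975) - np.quantile(g, 0.025) for g in grouped]
        )
        assert np.allclose(ranges, manual, atol=1e-10)
        assert v == pytest.approx(manual.mean(), abs=1e-10)


class TestSimulatePaths:
    def test_degenerate_dynamics_constant_at_last_score(self, wiener_spec):
        obs_cfg = ObservationModelConfig(sigma_y=0.01)
        phi = np.array([inverse_link(7.0, obs_cfg), -20.0])
        paths = simulate_paths(
            phi[None, :], np.array([0.01]), np.array([0.0]), np.array([7]),
            wiener_spec, obs_cfg, horizon=30, n_paths_per_draw=50,
            rng=np.random.default_rng(1),
        )
        assert np.all(paths == 7)

    def test_deterministic_given_rng_seed(self, wiener_spec, obs_cfg):
        phi = np.array([[0.0, -1.0], [0.3, -0.7]])
        args = (phi, np.array([2.0, 2.0]), np.array([0.0, 8.0]), np.array([25, 22]),
                wiener_spec, obs_cfg, 20, 10)
        a = simulate_paths(*args, rng=np.random.default_rng(9))
        b = simulate_paths(*args, rng=np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_latent_variance_grows_linearly(self, wiener_spec):
        """Score variance growth tracks exp(2 phi2) through the near-linear
        region of the link around the midpoint."""
        obs_cfg = ObservationModelConfig(sigma_y=0.5)
        phi2 = np.log(0.05)
        paths = simulate_paths(
            np.array([[0.0, phi2]]), np.array([0.5]), np.array([0.0]), np.array([25]),
            wiener_spec, obs_cfg, horizon=60, n_paths_per_draw=6000,
            rng=np.random.default_rng(3),
        ).astype(float)
        var_d = paths[0].var(axis=0)
        days = np.arange(1, 61)
        slope = np.polyfit(days, var_d, 1)[0]
        link_slope = 50.0 / 4.0  # logistic derivative at the midpoint
        assert slope == pytest.approx(link_slope**2 * np.exp(2 * phi2), rel=0.10)

    def test_summary_band_nesting(self, wiener_spec, obs_cfg):
        phi = np.tile(np.array([[0.0, -0.8]]), (8, 1))
        paths = simulate_paths(
            phi, np.full(8, 2.0), np.array([0.0]), np.array([25]),
            wiener_spec, obs_cfg, horizon=60, n_paths_per_draw=40,
            rng=np.random.default_rng(4),
        )
        s = summarize_paths(paths)
        assert np.all(s.daily_eti95_lo <= s.daily_eti68_lo)
        assert np.all(s.daily_eti68_lo <= s.daily_median)
        assert np.all(s.daily_median <= s.daily_eti68_hi)
        assert np.all(s.daily_eti68_hi <= s.daily_eti95_hi)
        assert 0.0 <= s.ihip <= 1.0
        assert 1 <= s.fut_days <= 60


def _fake_samples(phi2_true, rng, spread=0.2, n_draws=200, spec=None):
    spec = spec or ModelSpec.from_variant(2)
    M = phi2_true.size
    phi = np.empty((n_draws, M, 2))
    phi[:, :, 0] = rng.normal(-1.0, 0.1, size=(n_draws, M))
    phi[:, :, 1] = phi2_true[None, :] + spread * rng.standard_normal((n_draws, M))
    return PosteriorSamples(
        spec=spec,
        individual_ids=[f"ind{m:04d}" for m in range(M)],
        phi=phi,
        mu=np.tile(np.array([-1.0, -1.2]), (n_draws, 1)),
        tau=np.tile(np.array([1.0, 0.5]), (n_draws, 1)),
        sigma_y=np.full(n_draws, 2.0),
        increments=np.zeros((n_draws, 0)),
        obs_slices={},
        accept_rate={},
    )


class TestCovariateAssociation:
    def test_constant_covariate_rejected(self, rng):
        samples = _fake_samples(rng.normal(size=20), rng)
        cov = pd.DataFrame({"flat": np.ones(20)}, index=samples.individual_ids)
        with pytest.raises(ValueError, match="flat"):
            covariate_association(samples, cov)

    def test_null_covariate_interval_usually_contains_zero(self, rng):
        """Independent covariates: small mean correlation, ETIs straddle 0.

        The per-draw correlation interval reflects posterior uncertainty in
        phi2 only, so a finite-cohort chance correlation can push single
        replicates off zero; the check is over replicated null covariates.
        """
        samples = _fake_samples(rng.normal(size=40), rng, spread=0.7)
        contains = 0
        means = []
        for _ in range(12):
            cov = pd.DataFrame({"noise": rng.normal(size=40)}, index=samples.individual_ids)
            out = covariate_association(samples, cov)
            assert out.loc["noise", "kind"] == "correlation"
            means.append(out.loc["noise", "mean"])
            contains += out.loc["noise", "eti_lo"] < 0 < out.loc["noise", "eti_hi"]
        assert contains >= 8
        assert abs(np.mean(means)) < 0.15

    def test_binary_group_shift_recovered(self, rng):
        group = np.repeat([0.0, 1.0], 20)
        phi2 = rng.normal(-1.5, 0.3, size=40) + 0.5 * group
        samples = _fake_samples(phi2, rng, spread=0.1)
        cov = pd.DataFrame({"grp": group}, index=samples.individual_ids)
        out = covariate_association(samples, cov)
        assert out.loc["grp", "kind"] == "binary-difference"
        width = out.loc["grp", "eti_hi"] - out.loc["grp", "eti_lo"]
        assert out.loc["grp", "mean"] == pytest.approx(
            phi2[group == 1].mean() - phi2[group == 0].mean(), abs=width
        )


class TestPriorPredictiveBaseline:
    def test_collapsed_population_is_degenerate(self, wiener_spec, rng):
        obs_cfg = ObservationModelConfig(sigma_y=1e-6)
        pop = PopulationParams(mu=np.array([-1.0, -1.2]), tau=np.array([1e-9, 1e-9]), sigma_y=1e-6)
        out = prior_predictive_baseline(pop, wiener_spec, obs_cfg, 500, rng)
        from sidetraj import link_mean

        expected = int(np.round(link_mean(-1.0, obs_cfg)))
        assert np.all(out["y0_draws"] == expected)

    def test_draws_in_score_range_and_quantile_crosscheck(self, wiener_spec, obs_cfg, rng):
        pop = PopulationParams(mu=np.array([-1.0, -1.2]), tau=np.array([1.5, 0.7]), sigma_y=2.0)
        out = prior_predictive_baseline(pop, wiener_spec, obs_cfg, 5000, rng)
        y0 = out["y0_draws"]
        assert y0.min() >= 0 and y0.max() <= 50
        assert out["y0_median"] == pytest.approx(np.percentile(y0, 50), abs=1e-9)
        assert out["phi2_median"] == pytest.approx(np.percentile(out["phi2_draws"], 50), abs=1e-9)


class TestUpdateIndividual:
    def test_deterministic_given_seed(self, wiener_spec):
        pop = PopulationParams(mu=np.array([-1.0, -1.2]), tau=np.array([1.0, 0.5]), sigma_y=2.0)
        cfg = SamplerConfig(iterations=60, burnin=20, n_particles=20, seed=4)
        t = np.array([0.0, 10.0])
        y = np.array([3, 5])
        _, a = update_individual(pop, t, y, wiener_spec, cfg, n_param_draws=10, n_paths_per_draw=5)
        _, b = update_individual(pop, t, y, wiener_spec, cfg, n_param_draws=10, n_paths_per_draw=5)
        assert np.array_equal(a.daily_median, b.daily_median)
        assert a.ihip == b.ihip

    def test_bands_tighten_as_observations_accrue(self, wiener_spec):
        """A stable individual's day-30 95% band narrows from 1 to 10 obs."""
        obs_cfg = ObservationModelConfig()
        pop = PopulationParams(mu=np.array([-1.0, -1.2]), tau=np.array([1.0, 0.8]), sigma_y=2.0)
        t = np.arange(10) * 14.0
        y = np.full(10, 8)  # persistently moderate, low-variability course
        cfg = SamplerConfig(iterations=250, burnin=100, n_particles=50, seed=0)
        widths = {1: [], 10: []}
        for rep in range(4):
            for n in (1, 10):
                cfg_rep = SamplerConfig(iterations=250, burnin=100, n_particles=50, seed=rep)
                _, s = update_individual(
                    pop, t[:n], y[:n], wiener_spec, cfg_rep,
                    n_param_draws=60, n_paths_per_draw=15,
                )
                widths[n].append(s.daily_eti95_hi[29] - s.daily_eti95_lo[29])
        assert np.mean(widths[10]) < np.mean(widths[1])

    def test_empty_prefix_rejected(self, wiener_spec):
        pop = PopulationParams(mu=np.array([-1.0, -1.2]), tau=np.array([1.0, 0.5]))
        with pytest.raises(ValueError):
            update_individual(pop, np.array([]), np.array([]), wiener_spec, SamplerConfig(iterations=10, burnin=1))
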