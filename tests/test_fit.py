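"""Bayesian MSD fitting: likelihood, grid and MCMC posteriors, intervals."""

import numpy as np
import pytest

from glediff import (
    FitConfig,
    GLEFit,
    GLEParameters,
    ObservableCurve,
    ParameterDomainError,
    credible_interval,
    log_likelihood,
    noisy_msd,
    observable,
    posterior_grid,
    posterior_mcmc,
    reduced_chi2,
)

TRUTH = GLEParameters(M=41697.0, T=310.0, omega_s=0.98, omega_p=447.0,
                      tau=13.4e3, lam=0.715, nu=0.715, delta=1.0)
THETA_TRUE = np.array([0.98, 447.0, 13.4e3, 0.715])


def make_data(seed=101, n=120, sigma_rel=0.02):
    lags = np.geomspace(0.1, 5e6, n)
    return noisy_msd(TRUTH, lags, sigma_rel, seed=seed)


def small_config(**over):
    kwargs = dict(variant="M2", sigma_rel=0.02, grid_points=11, refine=8,
                  talbot_nodes=16)
    kwargs.update(over)
    return FitConfig(**kwargs)


class TestLikelihood:
    def test_maximal_at_generating_parameters(self):
        clean = make_data(sigma_rel=0.0)
        cfg = small_config()
        ll_true = log_likelihood(THETA_TRUE, clean, cfg)
        for bump in ([1.1, 1, 1, 1], [1, 0.9, 1, 1], [1, 1, 1.2, 1], [1, 1, 1, 0.95]):
            ll = log_likelihood(THETA_TRUE * np.asarray(bump), clean, cfg)
            assert ll < ll_true

    def test_doubling_sigma_shifts_minus_two_loglike(self):
        """-2 logL = chi^2 + 2 sum log sigma + n log 2pi: doubling sigma
        divides chi^2 by 4 and adds 2 n log 2."""
        data = make_data()
        cfg1 = small_config(sigma_rel=0.02)
        cfg2 = small_config(sigma_rel=0.04)
        n = len(data.times)
        m2l_1 = -2.0 * log_likelihood(THETA_TRUE, data, cfg1)
        m2l_2 = -2.0 * log_likelihood(THETA_TRUE, data, cfg2)
        chi2_1 = reduced_chi2(THETA_TRUE, data, cfg1) * (n - 4)
        expected = m2l_1 - 0.75 * chi2_1 + n * np.log(4.0)
        assert m2l_2 == pytest.approx(expected, rel=1e-12)

    def test_chi2_at_truth_is_chi2_distributed(self):
        """chi^2 at the generating parameters ~ n +- sqrt(2n)."""
        data = make_data(seed=77, n=300)
        cfg = small_config()
        n = len(data.times)
        chi2 = reduced_chi2(THETA_TRUE, data, cfg) * (n - 4)
        assert abs(chi2 - n) <= 2.0 * np.sqrt(2.0 * n)

    def test_sigma_halved_quadruples_reduced_chi2(self):
        data = make_data(seed=5)
        a = reduced_chi2(THETA_TRUE, data, small_config(sigma_rel=0.02))
        b = reduced_chi2(THETA_TRUE, data, small_config(sigma_rel=0.01))
        assert b == pytest.approx(4.0 * a, rel=1e-12)

    def test_zero_residuals_give_zero_chi2(self):
        clean = make_data(sigma_rel=0.0)
        cfg = small_config()
        model = observable("msd", clean.times, TRUTH).values
        data = ObservableCurve(clean.times, model, "msd")
        assert reduced_chi2(THETA_TRUE, data, cfg) < 1e-6

    def test_out_of_bounds_theta_rejected(self):
        with pytest.raises(ParameterDomainError):
            log_likelihood([100.0, 447.0, 13.4e3, 0.715], make_data(), small_config())

    def test_bounds_must_respect_cm_region(self):
        with pytest.raises(ParameterDomainError):
            FitConfig(variant="M2", prior_bounds={"lam": (0.5, 1.5)})


class TestGridPosterior:
    def test_single_point_grid_is_delta(self):
        data = make_data()
        cfg = FitConfig(
            variant="M2", sigma_rel=0.02, grid_points=1, refine=0,
            prior_bounds={
                "omega_s": (0.98, 0.980001), "omega_p": (447.0, 447.001),
                "tau": (13.4e3, 13.4001e3), "lam": (0.715, 0.7150001),
            },
        )
        post = posterior_grid(data, cfg)
        g, w = post.marginals["tau"]
        assert len(g) == 1 and w[0] == pytest.approx(1.0)

    def test_recovers_generating_parameters(self):
        """Posterior means land near truth; 95% intervals cover it."""
        post = posterior_grid(make_data(seed=303, n=200), small_config())
        assert post.mean["tau"] == pytest.approx(13.4e3, rel=0.1)
        assert post.mean["lam"] == pytest.approx(0.715, rel=0.05)
        for name, true in zip(post.param_names, THETA_TRUE):
            lo, hi = post.ci95[name]
            assert lo <= post.mean[name] <= hi
        assert post.reduced_chi2 == pytest.approx(1.0, abs=0.35)

    def test_coverage_over_synthetic_replicates(self):
        """95% intervals cover the generating values in >= 16 of 20
        replicate synthetic datasets, per parameter (binomial tolerance
        around nominal coverage)."""
        counts = dict.fromkeys(["omega_s", "omega_p", "tau", "lam"], 0)
        cfg = small_config(grid_points=9, max_fit_points=100)
        for i in range(20):
            data = make_data(seed=9000 + i, n=100)
            post = posterior_grid(data, cfg)
            for name, true in zip(post.param_names, THETA_TRUE):
                lo, hi = post.ci95[name]
                counts[name] += int(lo <= true <= hi)
        assert all(c >= 16 for c in counts.values()), counts

    def test_derived_relations_hold_at_support_points(self):
        """omega_p = omega_0^2 tau etc. hold exactly at every support point
        (derived quantities are deterministic functions of theta)."""
        post = posterior_grid(make_data(), small_config(grid_points=7, refine=2))
        axes = post.axes
        mesh = np.meshgrid(*[axes[n] for n in post.param_names], indexing="ij")
        omega0_sq_tau = (mesh[1] / mesh[2]) * mesh[2]  # (wp/tau) * tau
        assert np.allclose(omega0_sq_tau, mesh[1], rtol=1e-14)

    def test_m1_delta_concentrates_near_one_on_m2_data(self):
        """Fitting the five-parameter flavour to data generated with
        delta = 1: the delta marginal concentrates near 1, pointing toward
        the four-parameter flavour.  The extra exponent trades off against
        lam along a ridge, so the scan follows the coarse-then-finer
        workflow: the scale parameters get the already-narrowed box of a
        previous scan while both exponents span their full CM range."""
        data = make_data(seed=404, n=100)
        cfg = FitConfig(
            variant="M1", sigma_rel=0.02, grid_points=11, refine=6,
            talbot_nodes=14, max_fit_points=100,
            prior_bounds={
                "omega_s": (0.8, 1.2), "omega_p": (350.0, 550.0),
                "tau": (8e3, 2.5e4), "lam": (0.5, 1.0), "delta": (0.5, 1.0),
            },
        )
        post = posterior_grid(data, cfg)
        assert post.mean["delta"] > 0.9
        g, w = post.marginals["delta"]
        assert g[np.argmax(w)] > 0.9
        assert post.reduced_chi2 < 1.3

    def test_model_unreachable_raises_diagnostic(self):
        t = np.geomspace(1.0, 1e4, 50)
        bogus = ObservableCurve(t, np.full(50, 1e12), "msd")
        cfg = small_config(sigma_rel=1e-9, refine=0, grid_points=3)
        with pytest.raises(ParameterDomainError):
            posterior_grid(bogus, cfg)


class TestMCMC:
    def test_matches_grid_posterior_means(self):
        """Grid and ensemble-sampler posteriors agree on a shared problem
        (within a conservative multiple of the posterior spread)."""
        data = make_data(seed=88, n=80)
        grid = posterior_grid(data, small_config(max_fit_points=80))
        mcmc = posterior_mcmc(
            data,
            small_config(max_fit_points=80, n_walkers=24, n_steps=1500),
            seed=11,
        )
        for i, n in enumerate(grid.param_names):
            sd = np.std(mcmc.samples[:, i])
            assert abs(grid.mean[n] - mcmc.mean[n]) <= 0.5 * sd, n

    def test_prior_only_run_gives_flat_marginals(self):
        """With likelihood ~ constant (huge sigma) the sampler reproduces
        the flat prior: linear-axis marginals are uniform within noise."""
        data = make_data(n=30)
        cfg = small_config(sigma_rel=1e6, n_walkers=30, n_steps=1200,
                           max_fit_points=30)
        post = posterior_mcmc(data, cfg, seed=21)
        lam = post.samples[:, post.param_names.index("lam")]
        lo, hi = 0.3, 1.0
        # thirds of the prior range should carry comparable mass
        thirds = np.histogram(lam, bins=3, range=(lo, hi))[0] / len(lam)
        assert np.all(np.abs(thirds - 1 / 3) < 0.1)

    def test_fixed_seed_reproducible(self):
        data = make_data(n=40)
        cfg = small_config(n_walkers=16, n_steps=200, max_fit_points=40)
        a = posterior_mcmc(data, cfg, seed=31)
        b = posterior_mcmc(data, cfg, seed=31)
        assert np.array_equal(a.samples, b.samples)


class TestCredibleInterval:
    def test_normal_shaped_marginal_recovers_quantiles(self):
        g = np.linspace(-6, 6, 4001)
        w = np.exp(-0.5 * g**2)
        lo, hi = credible_interval((g, w / w.sum()), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_symmetric_marginal_symmetric_interval(self):
        g = np.linspace(-1, 1, 201)
        w = 1.0 - g**2
        lo, hi = credible_interval((g, w / w.sum()), 0.9)
        assert lo == pytest.approx(-hi, abs=1e-12)

    def test_point_mass_degenerate(self):
        assert credible_interval(([3.0], [1.0]), 0.95) == (3.0, 3.0)

    def test_level_validation(self):
        with pytest.raises(ParameterDomainError):
            credible_interval(([1.0, 2.0], [0.5, 0.5]), 1.5)


class TestGLEFitEstimator:
    def test_sklearn_protocol(self):
        est = GLEFit(grid_points=5)
        params = est.get_params()
        assert params["variant"] == "M2"
        est.set_params(grid_points=7)
        assert est.grid_points == 7
        from sklearn.base import clone

        clone(est)  # must not raise

    def test_fit_predict_roundtrip(self):
        data = make_data(seed=55, n=80)
        est = GLEFit(variant="M2", grid_points=9, refine=6, sigma_rel=0.02,
                     talbot_nodes=14, max_fit_points=80)
        est.fit(data)
        assert est.params_.tau == pytest.approx(13.4e3, rel=0.15)
        pred = est.predict(data.times)
        assert np.max(np.abs(pred / data.values - 1.0)) < 0.15
        # fitted attributes exist
        for attr in ("posterior_", "mean_", "ci95_", "derived_", "reduced_chi2_"):
            assert hasattr(est, attr)

    def test_fit_accepts_arrays(self):
        data = make_data(n=60)
        est = GLEFit(grid_points=5, refine=2, talbot_nodes=12, max_fit_points=40)
        est.fit(data.times, data.values)
        assert est.params_.M == 41697.0

    def test_predict_before_fit_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            GLEFit().predict([1.0, 2.0])
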