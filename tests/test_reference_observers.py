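"""Analytic BKE observer, RWMH samplers, SLO, and the MCMC-IO reference."""

import numpy as np
import pytest
from scipy.stats import kstest

from erocio import (
    AmplitudePrior,
    BoxPrior,
    GaussianNoiseModel,
    ImagingSystem,
    LumpyModelParams,
    MCMCConfig,
    PixelGrid,
    UnsupportedUtilityError,
    UtilityFunction,
    analytic_io_bke,
    fit_slo,
    make_matched_filter_init,
    mcmc_io_quadratic,
    reference_signal,
    rwmh_bke,
    rwmh_bks,
    sample_lumpy,
    slo_apply,
    utility_weighted_posterior_mean,
)
from erocio.datasets import generate_dataset
from erocio.experiments import make_signal_family, make_theta_prior


@pytest.fixture(scope="module")
def bke_setup():
    import erocio

    cfg = erocio.bke_amplitude()
    s_ref = reference_signal(cfg.system(), 1.0, (32.0, 32.0))
    return cfg, s_ref, AmplitudePrior(9.0, 4.0)


class TestAnalyticIO:
    def test_orthogonal_data(self, bke_setup):
        cfg, s_ref, prior = bke_setup
        g = np.zeros_like(s_ref)  # s_ref^T g = 0
        t, a_hat = analytic_io_bke(g, s_ref, prior, cfg.sigma_n)
        assert t == 0.0
        expected = cfg.sigma_n**2 * 9.0 / (cfg.sigma_n**2 + 16.0 * (s_ref @ s_ref))
        assert a_hat == pytest.approx(expected, rel=1e-12)

    def test_worked_example_unit_projection(self, bke_setup):
        # mu_A=9, sigma_A=4, sigma_n=40, s_ref^T g = 1 -> T = 9 + 16/3200
        cfg, s_ref, prior = bke_setup
        g = s_ref / (s_ref @ s_ref)
        t, _ = analytic_io_bke(g, s_ref, prior, 40.0)
        assert t == pytest.approx(9.005, abs=1e-10)

    def test_depends_only_on_projection(self, bke_setup, rng):
        cfg, s_ref, prior = bke_setup
        g = rng.normal(size=s_ref.size)
        ortho = rng.normal(size=s_ref.size)
        ortho -= (ortho @ s_ref) / (s_ref @ s_ref) * s_ref
        t1, a1 = analytic_io_bke(g, s_ref, prior, cfg.sigma_n)
        t2, a2 = analytic_io_bke(g + 5 * ortho, s_ref, prior, cfg.sigma_n)
        assert t1 == pytest.approx(t2, rel=1e-9)
        assert a1 == pytest.approx(a2, rel=1e-9)

    def test_degenerate_reference_rejected(self, bke_setup):
        _, s_ref, prior = bke_setup
        with pytest.raises(ValueError):
            analytic_io_bke(np.zeros_like(s_ref), np.zeros_like(s_ref), prior, 40.0)


class TestRwmhBke:
    def test_conjugate_posterior_mean_and_variance(self, bke_setup):
        cfg, s_ref, prior = bke_setup
        ds = generate_dataset(cfg, 1, 0, seed=17)
        g = ds.images[0]
        fam = make_signal_family(cfg)
        mcfg = MCMCConfig(n_samples=5000, burn_in=1000, proposal_std_theta=3.0, seed=0)
        samples = rwmh_bke(g, prior, fam, cfg.sigma_n, mcfg)
        _, a_hat = analytic_io_bke(g, s_ref, prior, cfg.sigma_n)
        post_var = 16.0 * cfg.sigma_n**2 / (cfg.sigma_n**2 + 16.0 * (s_ref @ s_ref))
        # conservative effective sample size for the 3-SE band
        se = np.sqrt(post_var) / np.sqrt(samples.size / 10)
        assert abs(samples.mean() - a_hat) < 3 * se
        assert samples.var() == pytest.approx(post_var, rel=0.3)

    def test_prior_limit_recovers_uniform_prior(self):
        # overwhelming noise -> posterior ~ prior
        grid = PixelGrid(16, 16)
        sys = ImagingSystem(grid=grid, h=1.0, w_m=1.0)
        prior = BoxPrior(lo=(4.0,), hi=(12.0,))
        fam = lambda th: np.zeros(grid.n_pixels)  # noqa: E731 - flat likelihood
        g = np.zeros(grid.n_pixels)
        mcfg = MCMCConfig(n_samples=10_000, burn_in=500, proposal_std_theta=2.0, seed=1)
        samples = rwmh_bke(g, prior, fam, 1.0, mcfg)[:, 0]
        stat = kstest(samples, "uniform", args=(4.0, 8.0)).statistic
        assert stat < 0.05

    def test_nonpositive_chain_length_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_samples=0)


class TestRwmhBks:
    def test_joint_chain_tracks_signal_location(self):
        import erocio

        # note: the posterior is genuinely multimodal for some realizations
        # (a lump can mimic the signal); this case has a dominant correct mode
        cfg = erocio.lumpy_location("quadratic", 200.0)
        ds = generate_dataset(cfg, 1, 0, seed=26)
        prior = make_theta_prior(cfg)
        fam = make_signal_family(cfg)
        init = make_matched_filter_init(fam, prior)
        mcfg = MCMCConfig(
            n_samples=2000, burn_in=1000, proposal_std_theta=4.0, proposal_std_lump=4.0, seed=2
        )
        samples, reals = rwmh_bks(
            ds.images[0], prior, cfg.background_params(), cfg.sigma_n, mcfg,
            cfg.system(), fam, init_realization=ds.backgrounds[0],
            theta0=init(ds.images[0]),
        )
        assert len(reals) == samples.shape[0]
        # posterior mean lands near the true location at this noise level
        assert np.all(np.abs(samples.mean(axis=0) - ds.theta[0]) < 6.0)
        # lump count held fixed, centres stay inside the support
        for r in reals[:50]:
            assert r.N_b == ds.backgrounds[0].N_b
            assert np.all((r.centers > 0.5) & (r.centers < 64.5))

    def test_out_of_support_theta_rejected_not_error(self):
        import erocio

        cfg = erocio.lumpy_location("quadratic", 200.0)
        ds = generate_dataset(cfg, 1, 0, seed=29)
        prior = BoxPrior(lo=(16.0, 16.0), hi=(48.0, 48.0))
        fam = make_signal_family(cfg)
        mcfg = MCMCConfig(
            n_samples=200, burn_in=10, proposal_std_theta=50.0,  # mostly out-of-box
            proposal_std_lump=4.0, seed=3,
        )
        samples, _ = rwmh_bks(
            ds.images[0], prior, cfg.background_params(), cfg.sigma_n, mcfg,
            cfg.system(), fam, init_realization=ds.backgrounds[0],
        )
        assert np.all((samples > 16.0) & (samples < 48.0))


class TestUtilityWeightedPosteriorMean:
    def test_single_matching_sample_gives_one(self):
        for kind, param in (("gaussian", 3.0), ("quadratic", 100.0), ("l1", 20.0)):
            u = UtilityFunction(kind, param)
            assert utility_weighted_posterior_mean([2.0], [[2.0]], u) == 1.0

    def test_constant_utility_gives_one(self, rng):
        u = UtilityFunction("gaussian", np.inf)  # u == 1 for any finite error
        samples = rng.normal(size=(50, 2))
        assert utility_weighted_posterior_mean([0.0, 0.0], samples, u) == 1.0

    def test_quadratic_identity_at_sample_mean(self, rng):
        samples = rng.normal(size=(500, 2))
        u = UtilityFunction("quadratic", 50.0)
        got = utility_weighted_posterior_mean(samples.mean(axis=0), samples, u)
        expected = 1.0 - samples.var(axis=0).sum() / 50.0
        assert got == pytest.approx(expected, rel=1e-12)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            utility_weighted_posterior_mean([0.0], np.zeros((0, 1)), UtilityFunction("l1", 1.0))


@pytest.fixture(scope="module")
def toy_slo():
    """BKE-style SLO on a 16x16 grid with exact templates."""
    grid = PixelGrid(16, 16)
    sys = ImagingSystem(grid=grid, h=4.0, w_m=1.0)
    from erocio import GaussianSignalParams, signal_image

    def signal_fn(theta):
        return signal_image(sys, GaussianSignalParams(5.0, 1.5, tuple(theta)))

    theta_grid = np.array([[x, y] for x in range(4, 13) for y in range(4, 13)], dtype=float)
    n = grid.n_pixels
    model = fit_slo(
        noiseless_present=np.zeros((0, n)),
        theta_present=np.zeros((0, 2)),
        noiseless_absent=np.zeros((4, n)),
        theta_grid=theta_grid,
        sigma_n=2.0,
        signal_fn=signal_fn,
    )
    return model, signal_fn, theta_grid


class TestSLO:
    def test_zero_background_covariance_is_noise_only(self, toy_slo):
        model, _, _ = toy_slo
        n = model.templates.shape[1]
        np.testing.assert_allclose(model.precision @ (np.eye(n) * 4.0), np.eye(n), atol=1e-9)

    def test_precision_inverts_covariance(self):
        rng = np.random.default_rng(0)
        n = 64
        imgs = rng.normal(size=(300, n))
        model = fit_slo(
            np.zeros((0, n)), np.zeros((0, 1)), imgs,
            theta_grid=np.array([[0.0]]), sigma_n=1.0,
            signal_fn=lambda th: np.zeros(n),
        )
        b_bar = imgs.mean(axis=0)
        K = (imgs - b_bar).T @ (imgs - b_bar) / 299 + np.eye(n)
        assert np.linalg.norm(model.precision @ K - np.eye(n), 2) < 1e-6

    def test_noiseless_template_recovers_its_parameter(self, toy_slo):
        model, signal_fn, theta_grid = toy_slo
        theta0 = np.array([8.0, 10.0])
        g = signal_fn(theta0)  # noiseless mean image at theta0 (b_bar = 0)
        _, theta_hat = slo_apply(model, g)
        np.testing.assert_array_equal(theta_hat, theta0)

    def test_argmax_contract(self, toy_slo, rng):
        model, _, theta_grid = toy_slo
        g = rng.normal(size=model.templates.shape[1])
        t, theta_hat = slo_apply(model, g)
        gc = g - model.b_bar
        scores = model.templates_prec @ gc - model.half_quad + model.log_prior
        assert t == pytest.approx(scores.max(), rel=1e-12)
        np.testing.assert_array_equal(theta_hat, model.theta_grid[np.argmax(scores)])

    def test_constant_log_prior_shifts_t_not_estimate(self, toy_slo, rng):
        model, signal_fn, theta_grid = toy_slo
        n = model.templates.shape[1]
        g = rng.normal(size=n)
        t, th = slo_apply(model, g)
        shifted = fit_slo(
            np.zeros((0, n)), np.zeros((0, 2)), np.zeros((4, n)),
            theta_grid, 2.0, signal_fn=signal_fn,
            log_prior=np.full(theta_grid.shape[0], 3.7),
        )
        t2, th2 = slo_apply(shifted, g)
        np.testing.assert_array_equal(th, th2)
        assert t2 == pytest.approx(t + 3.7, rel=1e-9)

    def test_matched_filter_when_covariance_is_white(self, toy_slo, rng):
        model, _, _ = toy_slo
        g = rng.normal(size=model.templates.shape[1])
        # with K = sigma^2 I, ranking over templates is by correlation - 0.5||t||^2
        gc = g - model.b_bar
        corr = (model.templates - model.b_bar) @ gc / 4.0
        quad = 0.5 * np.einsum("ij,ij->i", model.templates - model.b_bar,
                               model.templates - model.b_bar) / 4.0
        _, theta_hat = slo_apply(model, g)
        np.testing.assert_array_equal(theta_hat, model.theta_grid[np.argmax(corr - quad)])


class TestMCMCIO:
    def test_non_quadratic_utility_rejected(self):
        with pytest.raises(UnsupportedUtilityError):
            mcmc_io_quadratic(
                np.zeros(4), AmplitudePrior(), None, 1.0,
                UtilityFunction("l1", 20.0), MCMCConfig(),
            )

    def test_bke_estimate_matches_conjugate_posterior(self, bke_setup):
        cfg, s_ref, prior = bke_setup
        ds = generate_dataset(cfg, 2, 0, seed=31)
        fam = make_signal_family(cfg)
        post_var = 16.0 * cfg.sigma_n**2 / (cfg.sigma_n**2 + 16.0 * (s_ref @ s_ref))
        for i in range(2):
            mcfg = MCMCConfig(n_samples=4000, burn_in=500, proposal_std_theta=3.0, seed=40 + i)
            t, theta_hat, log_lam, U = mcmc_io_quadratic(
                ds.images[i], prior, None, cfg.sigma_n,
                UtilityFunction("quadratic", 100.0), mcfg,
                signal_family=fam, n_inner=512,
            )
            _, a_hat = analytic_io_bke(ds.images[i], s_ref, prior, cfg.sigma_n)
            se = np.sqrt(post_var) / np.sqrt(4000 / 10)
            assert abs(theta_hat[0] - a_hat) < 3 * se
            assert U <= 1.0
            assert np.isfinite(t)

    def test_concentrated_posterior_gives_unit_utility_weight(self, bke_setup):
        # tiny noise -> posterior collapses -> U -> 1, theta_hat -> truth
        cfg, s_ref, prior = bke_setup
        ds = generate_dataset(cfg, 1, 0, seed=37, noiseless=True)
        g = ds.noiseless[0]
        fam = make_signal_family(cfg)
        mcfg = MCMCConfig(n_samples=2000, burn_in=500, proposal_std_theta=0.05, seed=0)
        _, theta_hat, _, U = mcmc_io_quadratic(
            g, prior, None, 0.5, UtilityFunction("quadratic", 100.0), mcfg,
            signal_family=fam, n_inner=64, theta0=ds.theta[0],
        )
        assert U > 0.999
        assert theta_hat[0] == pytest.approx(ds.theta[0, 0], abs=0.1)


class TestMatchedFilterInit:
    def test_box_prior_init_lands_in_box_near_signal(self):
        import erocio

        cfg = erocio.lumpy_location("quadratic", 200.0)
        ds = generate_dataset(cfg, 3, 0, seed=41)
        fam = make_signal_family(cfg)
        init = make_matched_filter_init(fam, make_theta_prior(cfg))
        for i in range(3):
            th0 = init(ds.images[i])
            assert np.all((th0 > 16.0) & (th0 < 48.0))

    def test_gaussian_prior_falls_back_to_prior_center(self):
        init = make_matched_filter_init(lambda th: np.zeros(4), AmplitudePrior(9.0, 4.0))
        assert init(np.zeros(4))[0] == 9.0
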