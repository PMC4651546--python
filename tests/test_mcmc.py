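"""Sampler correctness: exact conditionals, conjugacies, joint-distribution
(simulate/update/resimulate) calibration, convergence diagnostics."""

import numpy as np
import pytest

from cooccupancy import MCMCConfig, PriorConfig, gelman_rubin, run_mcmc
from cooccupancy.landscape import generate_landscape, scale_covariates
from cooccupancy.mcmc import (
    init_state,
    prepare_data,
    sweep,
    update_detection,
    update_latent_occupancy,
    update_random_effects_and_variances,
)
from cooccupancy.model import DetectionHistory, inv_logit
from cooccupancy.simulate import simulate_dataset


@pytest.fixture(scope="module")
def tiny_cov():
    grid, raw = generate_landscape(2, 2, seed=1)
    return scale_covariates(raw, grid)


def _tiny_setup(tiny_cov, y_h=0, y_b=0, k=7, weeks=1, config=None, seed=0):
    n = tiny_cov.n_cells
    history = DetectionHistory(
        y_bobcat=np.full((n, weeks), y_b),
        y_hare=np.full((n, weeks), y_h),
        k=np.full((n, weeks), k),
    )
    config = config or MCMCConfig.test_scale()
    data = prepare_data(history, tiny_cov, config)
    rng = np.random.default_rng(seed)
    state = init_state(data, config, rng)
    return history, data, state, rng, config


class TestLatentUpdate:
    def test_detection_forces_presence(self, tiny_cov):
        _, data, state, rng, _ = _tiny_setup(tiny_cov, y_h=3, y_b=2)
        for _ in range(50):
            update_latent_occupancy(state, data, rng)
            assert state.z_h.all() and state.z_b.all()

    def test_bayes_rule_for_undetected_cell(self, tiny_cov):
        # flat prior mu=1/2, p=1/2, K=7, neutral predator branch:
        # Pr(Z=1 | Y=0) = (1/2)(1/2)^7 / ((1/2)(1/2)^7 + 1/2) = 1/129
        _, data, state, rng, _ = _tiny_setup(tiny_cov, y_h=0, y_b=0, k=7)
        data.x[:] = 0.0
        data.u[:] = 0.0
        state.b_h = state.b1 = state.b0 = 0.0
        state.beta_h[:] = 0.0
        state.th1[:] = 0.0
        state.th0[:] = 0.0
        state.eps_h[:] = 0.0
        state.eps_b[:] = 0.0
        state.p_h[:] = 0.5
        state.p_b[:] = 0.0  # predator detection uninformative
        state.refresh_caches(data)
        draws = np.empty(20_000)
        for m in range(draws.size):
            update_latent_occupancy(state, data, rng)
            draws[m] = state.z_h[0, 0]
        p = 1.0 / 129.0
        se = np.sqrt(p * (1 - p) / draws.size)
        assert abs(draws.mean() - p) < 3 * se


class TestConjugateUpdates:
    def test_detection_posterior_beta_moments(self, tiny_cov):
        # one occupied week with Y=7 of K=7 -> Beta(8, 1), mean 8/9;
        # unoccupied exposure -> prior Beta(1, 1), mean 1/2
        config = MCMCConfig.test_scale(bobcat_detection="cell", hare_detection="cell")
        _, data, state, rng, _ = _tiny_setup(tiny_cov, y_h=0, y_b=0, k=7, config=config)
        data.y_h[0, 0] = 7
        state.z_h[:] = 0
        state.z_h[0, 0] = 1
        state.z_b[:] = 0
        m = 4000
        acc = np.zeros((m, 2))
        for i in range(m):
            update_detection(state, data, rng, PriorConfig())
            acc[i] = state.p_h[0], state.p_h[1]
        assert abs(acc[:, 0].mean() - 8 / 9) < 4 * np.sqrt((8 / 9) * (1 / 9) / 10 / m)
        assert abs(acc[:, 1].mean() - 0.5) < 4 * np.sqrt(1 / 12 / m)

    def test_variance_inverse_gamma_moments(self, tiny_cov):
        # with random effects pinned, sigma^2 | eps ~ IG(a + NT/2, b + SS/2)
        _, data, state, rng, _ = _tiny_setup(tiny_cov, weeks=2)
        priors = PriorConfig(sigma2_shape=3.0, sigma2_rate=1.0)
        state.eps_h = np.full((4, 2), 0.5)
        state.eps_b = np.full((4, 2), -0.25)
        state.scales["eps_h"] = state.scales["eps_b"] = 1e-14  # pin the effects
        state.refresh_caches(data)
        cfg = MCMCConfig.test_scale()
        m = 4000
        draws = np.empty((m, 2))
        for i in range(m):
            update_random_effects_and_variances(state, data, rng, priors, cfg)
            draws[i] = state.sig2_h, state.sig2_b
        a = 3.0 + 4.0  # NT/2 = 4
        for j, ss in enumerate((8 * 0.5**2, 8 * 0.25**2)):
            b = 1.0 + ss / 2
            mean = b / (a - 1)
            sd = mean / np.sqrt(a - 2)
            assert abs(draws[:, j].mean() - mean) < 5 * sd / np.sqrt(m)


class TestRunMcmc:
    def test_same_seed_bit_identical(self, tiny_cov):
        history, _, _ = simulate_dataset(tiny_cov, n_weeks=3, seed=4)
        cfg = MCMCConfig(n_chains=2, n_burn=30, n_iter=30, thin=2, seed=9)
        a = run_mcmc(history, tiny_cov, cfg)
        b = run_mcmc(history, tiny_cov, cfg)
        for name in a.params:
            np.testing.assert_array_equal(a.params[name], b.params[name])
        np.testing.assert_array_equal(a.z_hare, b.z_hare)
        np.testing.assert_array_equal(a.p_hare, b.p_hare)

    def test_no_effort_posterior_matches_prior(self, tiny_cov):
        # K = 0 everywhere: detection and indicators fall back to their priors
        n = tiny_cov.n_cells
        history = DetectionHistory(
            y_bobcat=np.zeros((n, 3), dtype=int),
            y_hare=np.zeros((n, 3), dtype=int),
            k=np.zeros((n, 3), dtype=int),
        )
        cfg = MCMCConfig(n_chains=2, n_burn=300, n_iter=900, thin=1, seed=13)
        samples = run_mcmc(history, tiny_cov, cfg)
        p_draws = samples.p_hare.ravel()
        assert abs(p_draws.mean() - 0.5) < 0.03  # Beta(1,1) mean
        w_mean = samples.flat("w").mean()
        assert abs(w_mean - 0.5) < 0.05

    def test_zeroed_covariate_column_has_even_inclusion_odds(self, small_covariates):
        cov = small_covariates
        cov2 = type(cov)(cov.data.copy(), cov.center, cov.scale, cov.grid)
        cov2.data["dist_water"] = 0.0  # carries no information either way
        history, _, _ = simulate_dataset(cov, n_weeks=5, seed=31)
        cfg = MCMCConfig(n_chains=2, n_burn=300, n_iter=900, thin=1, seed=17)
        samples = run_mcmc(history, cov2, cfg)
        w = samples.flat("w")
        for k in (4, 9):  # dist_water indicators in both predator blocks
            assert abs(w[:, k].mean() - 0.5) < 0.06


class TestJointDistributionCalibration:
    def test_simulate_update_resimulate_matches_prior(self, tiny_cov):
        """Alternating data simulation with one MCMC sweep leaves the prior
        invariant; marginal moments of parameters and latent states must match
        direct prior simulation (validates every conditional jointly)."""
        priors = PriorConfig(
            hare_slope_sd=1.0,
            bobcat_slope_sd=1.0,
            intercept_sd=1.0,
            sigma2_shape=3.0,
            sigma2_rate=1.0,
        )
        cfg = MCMCConfig.test_scale(
            bobcat_detection="constant", hare_detection="constant", seed=0
        )
        n = tiny_cov.n_cells
        T = 2
        history = DetectionHistory(
            y_bobcat=np.zeros((n, T), dtype=int),
            y_hare=np.zeros((n, T), dtype=int),
            k=np.full((n, T), 3),
        )
        data = prepare_data(history, tiny_cov, cfg)
        rng = np.random.default_rng(2024)
        state = init_state(data, cfg, rng)
        # start from an exact prior draw
        state.b_h = rng.normal(0, 1)
        state.b1, state.b0 = rng.normal(0, 1, 2)
        state.beta_h = rng.normal(0, 1, 9)
        state.th1, state.th0 = rng.normal(0, 1, 5), rng.normal(0, 1, 5)
        state.w = rng.integers(0, 2, 19)
        state.sig2_h = 1.0 / rng.gamma(3.0, 1.0)
        state.sig2_b = 1.0 / rng.gamma(3.0, 1.0)
        state.eps_h = rng.normal(0, np.sqrt(state.sig2_h), (n, T))
        state.eps_b = rng.normal(0, np.sqrt(state.sig2_b), (n, T))
        state.p_h = rng.beta(1, 1, data.ng_h)
        state.p_b = rng.beta(1, 1, data.ng_b)
        state.refresh_caches(data)
        state.z_h = (rng.random((n, T)) < inv_logit(state.eta_h)).astype(np.int8)
        mu_b = np.where(state.z_h == 1, inv_logit(state.eta1), inv_logit(state.eta0))
        state.z_b = (rng.random((n, T)) < mu_b).astype(np.int8)

        m = 4000
        rec = {k: np.empty(m) for k in ("b_h", "sig2_h", "sig2_b", "w", "z_h", "z_b")}
        for i in range(m):
            # resimulate data given the current latent state
            data.y_h[:] = rng.binomial(data.k, state.p_h[data.g_h] * state.z_h)
            data.y_b[:] = rng.binomial(data.k, state.p_b[data.g_b] * state.z_b)
            sweep(state, data, rng, priors, cfg, adapt=False)
            rec["b_h"][i] = state.b_h
            rec["sig2_h"][i] = state.sig2_h
            rec["sig2_b"][i] = state.sig2_b
            rec["w"][i] = state.w.mean()
            rec["z_h"][i] = state.z_h.mean()
            rec["z_b"][i] = state.z_b.mean()

        # prior-predictive reference for the occupancy frequency, forward MC
        ref_rng = np.random.default_rng(99)
        R = 4000
        zh_ref = np.empty(R)
        zb_ref = np.empty(R)
        x, u = data.x, data.u
        for r in range(R):
            s2h = 1.0 / ref_rng.gamma(3.0, 1.0)
            s2b = 1.0 / ref_rng.gamma(3.0, 1.0)
            wv = ref_rng.integers(0, 2, 19)
            eta_h = (
                ref_rng.normal(0, 1)
                + x @ (wv[10:] * ref_rng.normal(0, 1, 9))
            )[:, None] + ref_rng.normal(0, np.sqrt(s2h), (n, T))
            zh = (ref_rng.random((n, T)) < inv_logit(eta_h)).astype(float)
            eps = ref_rng.normal(0, np.sqrt(s2b), (n, T))
            eta1 = (ref_rng.normal(0, 1) + u @ (wv[:5] * ref_rng.normal(0, 1, 5)))[:, None] + eps
            eta0 = (ref_rng.normal(0, 1) + u @ (wv[5:10] * ref_rng.normal(0, 1, 5)))[:, None] + eps
            mu = np.where(zh == 1, inv_logit(eta1), inv_logit(eta0))
            zb = (ref_rng.random((n, T)) < mu).astype(float)
            zh_ref[r], zb_ref[r] = zh.mean(), zb.mean()

        assert abs(rec["b_h"].mean()) < 0.25  # prior N(0,1), autocorrelated chain
        assert abs(rec["b_h"].std() - 1.0) < 0.25
        assert abs(rec["sig2_h"].mean() - 0.5) < 0.12  # IG(3,1) mean
        assert abs(rec["sig2_b"].mean() - 0.5) < 0.12
        assert abs(rec["w"].mean() - 0.5) < 0.05
        assert abs(rec["z_h"].mean() - zh_ref.mean()) < 0.05
        assert abs(rec["z_b"].mean() - zb_ref.mean()) < 0.05


class TestGelmanRubin:
    def test_identical_chains_give_unity(self, rng):
        x = rng.normal(size=200)
        assert gelman_rubin(np.vstack([x, x])) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_constant_chains_diverge(self):
        chains = np.vstack([np.zeros(50), np.ones(50)])
        assert gelman_rubin(chains) == np.inf

    def test_hand_formula_on_fixed_draws(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        chains = np.vstack([base, base + 3.0])  # shifted means: R-hat > 1
        m, ndraw = chains.shape
        W = np.mean([np.var(c, ddof=1) for c in chains])
        B_over_n = np.var(chains.mean(axis=1), ddof=1)
        expected = np.sqrt(((ndraw - 1) / ndraw * W + B_over_n) / W)
        assert expected > 1.0
        assert gelman_rubin(chains) == pytest.approx(expected, rel=1e-12)

    def test_floored_at_one_when_pooled_variance_dips(self):
        chains = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0],
                           [2.0, 4.0, 6.0, 8.0, 10.0, 1.0, 3.0, 5.0, 7.0, 9.0]])
        assert gelman_rubin(chains) == 1.0

    def test_iid_chains_rarely_flag(self, rng):
        flagged = 0
        for _ in range(20):
            chains = rng.normal(size=(3, 1000))
            if gelman_rubin(chains) >= 1.05:
                flagged += 1
        assert flagged <= 1

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))
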