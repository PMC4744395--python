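"""Sampler machinery: initialization, HMC, determinism, summaries."""

import numpy as np
import pytest

from trex3d import geometry
from trex3d.inference import (MCMCConfig, PosteriorSamples, _State,
                              _leapfrog, fit, hmc_update,
                              initialize_structure, point_estimate,
                              posterior_distance_summary)
from trex3d.model_core import (ContactMatrix, CovariateSet, ModelParams,
                               Structure3D, log_intensity,
                               pairwise_distances, truncated_poisson_loglik)
from trex3d.simulator import SimulationConfig, simulate_dataset


@pytest.fixture(scope="module")
def fitted(gold):
    """One short tPAM fit on clean data, reused across tests."""
    cfg = SimulationConfig(model="NRE", pi=0.0)
    counts, cov = simulate_dataset(gold, cfg, seed=7)
    mc = MCMCConfig(n_iter=500, burn_in=200, rng_seed=11, mode="tpam")
    return counts, cov, mc, fit(counts, cov, mc)


class TestInitialization:
    def test_high_signal_recovery(self, gold):
        cfg = SimulationConfig(model="NRE", pi=0.0)
        counts, _ = simulate_dataset(gold, cfg, seed=3)
        init = initialize_structure(counts, beta1_init=-0.434)
        assert geometry.aligned_correlation(gold.structure, init) > 0.7

    def test_permutation_equivariance(self, gold, rng):
        cfg = SimulationConfig(model="NRE", pi=0.0)
        counts, _ = simulate_dataset(gold, cfg, seed=3)
        perm = rng.permutation(43)
        permuted = ContactMatrix(counts.counts[np.ix_(perm, perm)])
        a = initialize_structure(counts, -1.0, seed=0)
        b = initialize_structure(permuted, -1.0, seed=0)
        # same point cloud up to the canonical frame: compare distances
        da = pairwise_distances(a)[np.ix_(perm, perm)]
        db = pairwise_distances(b)
        assert np.allclose(da, db, rtol=1e-3, atol=1e-6)

    def test_equal_counts_give_regular_tetrahedron(self):
        c = np.full((4, 4), 7)
        np.fill_diagonal(c, 0)
        init = initialize_structure(ContactMatrix(c), -1.0)
        d = pairwise_distances(init)
        iu = np.triu_indices(4, 1)
        assert d[iu].std() / d[iu].mean() < 1e-3

    def test_disconnected_graph_warns(self):
        c = np.zeros((6, 6), dtype=int)
        c[0, 1] = c[1, 0] = 4
        c[1, 2] = c[2, 1] = 4
        c[3, 4] = c[4, 3] = 4
        c[4, 5] = c[5, 4] = 4
        with pytest.warns(UserWarning, match="disconnected"):
            initialize_structure(ContactMatrix(c), -1.0)


class TestHMC:
    def _setup(self, rng, n=5, beta0=4.0):
        # beta0 high enough that every pair has counts: a concentrated,
        # well-identified posterior (sampler agreement is then testable)
        coords = rng.standard_normal((n, 3))
        structure = Structure3D(coords)
        params = ModelParams(beta0=beta0, beta1=-0.8)
        d = pairwise_distances(structure)
        lam = np.exp(log_intensity(params, d))
        c = rng.poisson(lam)
        c = np.triu(c, 1)
        counts = ContactMatrix(c + c.T)
        return structure, params, counts

    def test_tiny_stepsize_always_accepts(self, rng):
        structure, params, counts = self._setup(rng)
        cfg = MCMCConfig(n_iter=10, burn_in=1, hmc_stepsize=1e-7,
                         hmc_steps=3, mode="tpam")
        accepts = [hmc_update(structure, params, None, counts, None, cfg,
                              np.random.default_rng(k))[1]
                   for k in range(20)]
        assert all(accepts)

    def test_energy_error_scales_quadratically(self, rng):
        """Halving the leapfrog stepsize cuts the Hamiltonian error by
        about 4x (second-order integrator)."""
        structure, params, counts = self._setup(rng, n=6)
        cfg = MCMCConfig(mode="tpam", beta0=params.beta0,
                         beta1_init=params.beta1)
        state = _State(counts, None, cfg, structure.coords, center_x=False)
        errors = []
        for eps, steps in ((0.02, 10), (0.01, 20)):  # fixed trajectory length
            errs = []
            for k in range(40):
                r = np.random.default_rng(k)
                mom = r.standard_normal((6, 3))
                ll0, _ = state.coord_loglik_grad(state.coords)
                h0 = -ll0 + 0.5 * np.sum(mom ** 2)
                q, p, ll1 = _leapfrog(state, state.coords, mom, eps, steps)
                h1 = -ll1 + 0.5 * np.sum(p ** 2)
                errs.append(abs(h1 - h0))
            errors.append(np.mean(errs))
        ratio = errors[0] / errors[1]
        assert 2.5 < ratio < 6.5

    def test_matches_random_walk_sampler(self, rng):
        """Long-run mean log-likelihood agrees between HMC and an
        independent random-walk Metropolis sampler on the same target."""
        structure, params, counts = self._setup(rng, n=5)
        cfg = MCMCConfig(mode="tpam", beta0=params.beta0,
                         beta1_init=params.beta1,
                         hmc_stepsize=0.03, hmc_steps=10)
        state = _State(counts, None, cfg, structure.coords, center_x=False)

        # HMC chain
        r = np.random.default_rng(1)
        cur = Structure3D(structure.coords.copy())
        hmc_lls = []
        for _ in range(3000):
            cur, _acc = hmc_update(cur, params, None, counts, None, cfg, r)
            ll, _ = state.coord_loglik_grad(cur.coords)
            hmc_lls.append(ll)

        # independent random-walk MH oracle on the same log-target
        r2 = np.random.default_rng(2)
        coords = structure.coords.copy()
        ll_cur, _ = state.coord_loglik_grad(coords)
        rw_lls = []
        for _ in range(60_000):
            prop = coords + 0.05 * r2.standard_normal(coords.shape)
            ll_prop, _ = state.coord_loglik_grad(prop)
            if np.log(r2.random()) < ll_prop - ll_cur:
                coords, ll_cur = prop, ll_prop
            rw_lls.append(ll_cur)
        a = np.mean(hmc_lls[500:])
        b = np.mean(rw_lls[10_000:])
        se = np.std(rw_lls[10_000:]) / 30  # generous MC error allowance
        assert a == pytest.approx(b, abs=max(3 * se, 1.5))


class TestFit:
    def test_deterministic_given_seed(self, gold):
        cfg = SimulationConfig(model="NRE", pi=0.3)
        counts, cov = simulate_dataset(gold, cfg, seed=5)
        mc = MCMCConfig(n_iter=150, burn_in=50, rng_seed=9, mode="trex")
        s1 = fit(counts, cov, mc)
        s2 = fit(counts, cov, mc)
        assert np.array_equal(s1.coords, s2.coords)
        assert np.array_equal(s1.beta1, s2.beta1)
        assert np.array_equal(s1.sigma2_u, s2.sigma2_u)

    def test_stored_structures_are_canonical(self, fitted):
        _, _, _, samples = fitted
        for k in range(0, samples.n_draws, 50):
            s = Structure3D(samples.coords[k])
            canon, _ = geometry.canonicalize(s)
            assert np.allclose(canon.coords, s.coords, atol=1e-8)

    def test_beta1_draws_negative(self, fitted):
        _, _, _, samples = fitted
        assert np.all(samples.beta1 < 0)

    def test_loglik_trace_stationary_after_burnin(self, gold):
        """Geweke-style check: the split means of the post-burn-in
        log-likelihood trace agree within Monte-Carlo error."""
        cfg = SimulationConfig(model="NRE", pi=0.0)
        counts, cov = simulate_dataset(gold, cfg, seed=7)
        mc = MCMCConfig(n_iter=3000, burn_in=1500, rng_seed=2, mode="tpam")
        samples = fit(counts, cov, mc)
        trace = samples.loglik
        k = trace.size
        a, b = trace[: k // 4], trace[-k // 2:]

        def batch_se(x, nb=12):
            means = [m.mean() for m in np.array_split(x, nb)]
            return np.std(means, ddof=1) / np.sqrt(nb)

        z = (a.mean() - b.mean()) / np.hypot(batch_se(a), batch_se(b))
        assert abs(z) < 3.0

    def test_tpam_is_trex_with_pinned_variances(self, gold):
        """Identical states give identical likelihood values whether the
        random-effect machinery is present (at zero) or absent."""
        cfg = SimulationConfig(model="NRE", pi=0.3)
        counts, cov = simulate_dataset(gold, cfg, seed=5)
        c_tpam = MCMCConfig(mode="tpam", beta1_init=-0.7)
        c_trex = MCMCConfig(mode="trex", beta1_init=-0.7)
        coords = initialize_structure(counts, -0.7).coords
        s1 = _State(counts, cov, c_tpam, coords)
        s2 = _State(counts, cov, c_trex, coords)  # X = U = 0 initially
        assert s1.loglik() == pytest.approx(s2.loglik(), abs=1e-12)

    def test_all_zero_matrix_rejected(self):
        counts = ContactMatrix(np.zeros((5, 5), dtype=int))
        with pytest.raises(ValueError, match="all-zero"):
            fit(counts, None, MCMCConfig(n_iter=10, burn_in=1))

    def test_fit_without_covariates_runs(self, gold):
        cfg = SimulationConfig(model="NRE", pi=0.3)
        counts, _ = simulate_dataset(gold, cfg, seed=5)
        mc = MCMCConfig(n_iter=100, burn_in=40, rng_seed=1, mode="tpam")
        samples = fit(counts, None, mc)
        assert samples.n_draws == 60
        assert np.all(samples.gamma1 == 0.0)


class TestPointEstimate:
    def test_identical_draws(self, rng):
        coords = geometry.canonicalize(
            Structure3D(rng.standard_normal((6, 3))))[0].coords
        s = PosteriorSamples(
            coords=np.repeat(coords[None], 5, axis=0),
            beta1=-np.ones(5), gamma1=np.zeros(5), gamma2=np.zeros(5),
            sigma2_x=np.zeros(5), sigma2_u=np.zeros(5),
            loglik=np.arange(5.0))
        est = point_estimate(s)
        assert np.allclose(est.coords, coords, atol=1e-10)
        est2 = point_estimate(s, mode="max_loglik")
        assert np.allclose(est2.coords, coords, atol=1e-10)

    def test_mean_converges_under_symmetric_noise(self, rng):
        base = geometry.canonicalize(
            Structure3D(rng.standard_normal((8, 3)) * 3))[0].coords
        draws = base[None] + 0.01 * rng.standard_normal((4000, 8, 3))
        s = PosteriorSamples(
            coords=draws, beta1=-np.ones(4000), gamma1=np.zeros(4000),
            gamma2=np.zeros(4000), sigma2_x=np.zeros(4000),
            sigma2_u=np.zeros(4000), loglik=np.zeros(4000))
        est = point_estimate(s)
        err = geometry.rmsd(Structure3D(base), est)
        assert err < 0.002

    def test_empty_samples_rejected(self):
        s = PosteriorSamples(
            coords=np.empty((0, 4, 3)), beta1=np.empty(0),
            gamma1=np.empty(0), gamma2=np.empty(0), sigma2_x=np.empty(0),
            sigma2_u=np.empty(0), loglik=np.empty(0))
        with pytest.raises(ValueError):
            point_estimate(s)


class TestDistanceSummary:
    def _samples(self, coords):
        k = coords.shape[0]
        return PosteriorSamples(
            coords=coords, beta1=-np.ones(k), gamma1=np.zeros(k),
            gamma2=np.zeros(k), sigma2_x=np.zeros(k), sigma2_u=np.zeros(k),
            loglik=np.zeros(k))

    def test_single_draw_median(self, rng):
        coords = rng.standard_normal((1, 5, 3))
        s = self._samples(coords)
        out = posterior_distance_summary(s, [(0, 1)])
        expect = np.linalg.norm(coords[0, 0] - coords[0, 1])
        assert out["median"].iloc[0] == pytest.approx(expect)

    def test_known_median(self):
        coords = np.zeros((3, 4, 3))
        coords[0, 1, 0] = 1.0
        coords[1, 1, 0] = 2.0
        coords[2, 1, 0] = 3.0
        out = posterior_distance_summary(self._samples(coords), [(0, 1)])
        assert out["median"].iloc[0] == pytest.approx(2.0)

    def test_quantiles_match_sorting(self, rng):
        coords = rng.standard_normal((101, 6, 3))
        s = self._samples(coords)
        out = posterior_distance_summary(s, [(2, 4)], quantiles=(0.25, 0.75))
        d = np.linalg.norm(coords[:, 2] - coords[:, 4], axis=1)
        assert out["q0.25"].iloc[0] == pytest.approx(np.quantile(d, 0.25))
        assert out["q0.75"].iloc[0] == pytest.approx(np.quantile(d, 0.75))

    def test_invalid_pair(self, rng):
        s = self._samples(rng.standard_normal((3, 5, 3)))
        with pytest.raises(ValueError):
            posterior_distance_summary(s, [(0, 9)])
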