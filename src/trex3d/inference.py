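"""Bayesian inference for the truncated Poisson structure models.

The posterior over the 3D coordinates and model parameters is explored
with a Metropolis-within-Gibbs sampler:

* coordinates: Hamiltonian Monte Carlo (leapfrog trajectories on the
  truncated-Poisson log-likelihood, which is differentiable in the
  coordinates) — gradient guidance is essential because the ``3n``
  coordinates are strongly correlated a posteriori;
* ``beta1``: random-walk Metropolis on ``log(-beta1)``, which enforces
  the negativity constraint without boundary handling;
* covariate coefficients ``gamma1, gamma2``: scalar random-walk
  Metropolis;
* latent effects ``X_i`` (per locus) and ``U_ij`` (per nonzero pair):
  random-walk Metropolis, ``U`` updated for all pairs at once (their
  likelihood terms do not interact);
* random-effect variances: conjugate inverse-gamma Gibbs draws.

``beta0`` is held fixed (default 3): it only sets the overall scale of
the structure, which is not identifiable from contact data.  The
coordinates are sampled unconstrained; every retained draw is mapped
through the canonical isometry for storage, so all stored structures
satisfy the identifiability constraints.  tPAM is the same machinery
with the random-effect variances pinned at zero.

Priors (weakly informative): ``beta1 ~ N(0, 10^2)`` truncated to the
negative axis, ``gamma ~ N(0, 10^2)``, variances ~ InvGamma(2, 0.1).
The coordinates get an isotropic Gaussian prior whose SD is a multiple
(default 3) of the RMS radius of the initialization: a completely flat
coordinate prior makes the tREX posterior improper — a power-stretch of
the distances can be traded against ``beta1`` and absorbed by the
pair-level latents at finite cost while the coordinate volume grows
without bound — and the weak Gaussian prior closes exactly that escape
while leaving local inference essentially untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path

from . import geometry
from .model_core import (ContactMatrix, CovariateSet, ModelParams,
                         RandomEffects, Structure3D, nonzero_pairs,
                         pairwise_distances)

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "fit",
    "initialize_structure",
    "hmc_update",
    "point_estimate",
    "posterior_distance_summary",
]


@dataclass
class MCMCConfig:
    """Sampler settings.  Runs are bit-reproducible given ``rng_seed``."""

    n_iter: int = 15_000
    burn_in: int = 5_000
    thin: int = 1
    mode: str = "trex"  # "trex" | "tpam"
    beta0: float = 3.0
    beta1_init: float = -1.0
    hmc_steps: int = 10
    hmc_stepsize: float = 0.002
    scale_beta1: float = 0.05  # RW scale on log(-beta1)
    scale_gamma: float = 0.05
    scale_expand: float = 0.05  # RW scale of the log structure-scale move
    scale_x: float = 0.1
    scale_u: float = 0.2
    coord_prior_factor: float = 1.5  # prior SD in units of init RMS radius
    latent_warmup_frac: float = 0.5  # fraction of burn-in before latents move
    prior_sd_beta1: float = 10.0
    prior_sd_gamma: float = 10.0
    prior_ig_shape: float = 2.0
    prior_ig_scale: float = 0.1
    adapt: bool = True
    estimate_gamma: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_iter > self.burn_in >= 0):
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.hmc_stepsize <= 0:
            raise ValueError("hmc_stepsize must be positive")
        if self.mode not in ("trex", "tpam"):
            raise ValueError("mode must be 'trex' or 'tpam'")
        if not self.beta1_init < 0:
            raise ValueError("beta1_init must be negative")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws; every stored structure is canonical."""

    coords: np.ndarray       # (k, n, 3), canonicalized
    beta1: np.ndarray        # (k,)
    gamma1: np.ndarray
    gamma2: np.ndarray
    sigma2_x: np.ndarray
    sigma2_u: np.ndarray
    loglik: np.ndarray       # (k,)
    accept_rates: dict = field(default_factory=dict)
    config: MCMCConfig | None = None

    @property
    def n_draws(self) -> int:
        return self.coords.shape[0]

    @property
    def n_loci(self) -> int:
        return self.coords.shape[1]


def _log_expm1(lam: np.ndarray) -> np.ndarray:
    lam = np.maximum(lam, 1e-12)
    return lam + np.log1p(-np.exp(-lam))


def _trunc_terms(y: np.ndarray, ll: np.ndarray) -> np.ndarray:
    """Per-pair truncated-Poisson log-likelihood terms."""
    return y * ll - _log_expm1(np.exp(ll))


def _grad_loglam(y: np.ndarray, ll: np.ndarray) -> np.ndarray:
    lam = np.exp(ll)
    return y - lam / (-np.expm1(-np.maximum(lam, 1e-12)))


class _State:
    """Mutable sampler state over the nonzero-pair index set."""

    def __init__(self, counts: ContactMatrix, covariates: CovariateSet | None,
                 config: MCMCConfig, coords: np.ndarray,
                 center_x: bool = True):
        self.center_x = center_x
        self.rows, self.cols = nonzero_pairs(counts)
        if self.rows.size == 0:
            raise ValueError("all-zero contact matrix: nothing to fit")
        self.y = counts.counts[self.rows, self.cols].astype(float)
        self.tau2 = None  # coordinate prior variance; None = flat
        self.n = counts.n_loci
        self.m = self.rows.size
        self.beta0 = config.beta0
        self.coords = coords.astype(float).copy()
        self.beta1 = config.beta1_init
        self.gamma1 = 0.0
        self.gamma2 = 0.0
        self.trex = config.mode == "trex"
        self.X = np.zeros(self.n)
        self.U = np.zeros(self.m)
        self.sigma2_x = 0.01 if self.trex else 0.0
        self.sigma2_u = 0.01 if self.trex else 0.0
        if covariates is not None:
            lz_l, lz_g, lz_m = (np.log(covariates.z_l), np.log(covariates.z_g),
                                np.log(covariates.z_m))
            # center the pair covariate terms: with narrow-range
            # covariates their mean acts as a free intercept that would
            # destroy the scale identification provided by the fixed
            # beta0 (equivalent to redefining the arbitrary intercept)
            self.cl = lz_l[self.rows] + lz_l[self.cols]
            self.cg = lz_g[self.rows] + lz_g[self.cols]
            self.cm = lz_m[self.rows] + lz_m[self.cols]
            if center_x:
                self.cl -= self.cl.mean()
                self.cg -= self.cg.mean()
                self.cm -= self.cm.mean()
        else:
            self.cl = self.cg = self.cm = np.zeros(self.m)
        # incidence: pair indices touching each locus
        self.incident = [np.flatnonzero((self.rows == i) | (self.cols == i))
                         for i in range(self.n)]
        deg = np.array([idx.size for idx in self.incident])
        if np.any(deg == 0):
            warnings.warn(
                f"{int(np.sum(deg == 0))} locus/loci have no nonzero "
                "contacts; their coordinates are only weakly identified",
                stacklevel=3)
        self._refresh_distances()

    # -- cached per-pair quantities ------------------------------------
    def _refresh_distances(self) -> None:
        diff = self.coords[self.rows] - self.coords[self.cols]
        self.logd = 0.5 * np.log(np.einsum("ij,ij->i", diff, diff))

    def w_pairs(self) -> np.ndarray:
        # the locus effects enter centered: their grand mean is another
        # free intercept that would leak the scale identification (see
        # the covariate centering above); sum-to-zero removes it
        x = self.X - self.X.mean() if self.center_x else self.X
        return x[self.rows] + x[self.cols] + self.U

    def loglam(self, logd=None, beta1=None, gamma1=None, gamma2=None,
               w=None) -> np.ndarray:
        logd = self.logd if logd is None else logd
        beta1 = self.beta1 if beta1 is None else beta1
        gamma1 = self.gamma1 if gamma1 is None else gamma1
        gamma2 = self.gamma2 if gamma2 is None else gamma2
        w = (self.w_pairs() if self.trex else 0.0) if w is None else w
        return (self.beta0 + beta1 * logd + gamma1 * self.cl
                + gamma2 * self.cg + self.cm + w)

    def loglik(self, **kw) -> float:
        return float(np.sum(_trunc_terms(self.y, self.loglam(**kw))))

    def coord_loglik_grad(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        """Log-likelihood and its coordinate gradient at given coords."""
        diff = coords[self.rows] - coords[self.cols]
        sq = np.einsum("ij,ij->i", diff, diff)
        logd = 0.5 * np.log(sq)
        ll = self.loglam(logd=logd)
        g = _grad_loglam(self.y, ll) * self.beta1 / sq
        contrib = g[:, None] * diff
        grad = np.empty((self.n, 3))
        for k in range(3):
            grad[:, k] = (
                np.bincount(self.rows, weights=contrib[:, k], minlength=self.n)
                - np.bincount(self.cols, weights=contrib[:, k], minlength=self.n))
        total = float(np.sum(_trunc_terms(self.y, ll)))
        if self.tau2 is not None:
            total -= 0.5 * float(np.sum(coords ** 2)) / self.tau2
            grad -= coords / self.tau2
        return total, grad


def initialize_structure(counts: ContactMatrix,
                         beta1_init: float = -1.0,
                         seed: int = 0) -> Structure3D:
    """Classical-MDS starting structure from surrogate distances.

    Nonzero counts are converted to surrogate distances
    ``(y_ij + 1)^(1/beta1_init)``; missing pairs are imputed by the
    shortest path over the graph of nonzero pairs (disconnected
    components are bridged with a large distance and a warning), and the
    resulting distance matrix is embedded in 3D by classical metric
    multidimensional scaling.  The output is canonicalized.
    """
    if not beta1_init < 0:
        raise ValueError("beta1_init must be negative")
    c = counts.counts
    n = counts.n_loci
    with np.errstate(divide="ignore"):
        d = np.where(c > 0, (c + 1.0) ** (1.0 / beta1_init), 0.0)
    sp = shortest_path(d, method="D", directed=False)
    if np.any(np.isinf(sp[np.triu_indices(n, k=1)])):
        warnings.warn("contact graph is disconnected; bridging components "
                      "with a large surrogate distance", stacklevel=2)
        finite = sp[np.isfinite(sp)]
        bridge = 3.0 * (finite.max() if finite.size else 1.0)
        sp[np.isinf(sp)] = bridge
    np.fill_diagonal(sp, 0.0)
    # classical MDS: double-centered squared distances
    d2 = sp ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:3]
    vals3 = np.maximum(vals[order], 1e-12)
    coords = vecs[:, order] * np.sqrt(vals3)
    # break exact degeneracies (e.g. perfectly planar embeddings)
    rng = np.random.default_rng(seed)
    coords = coords + 1e-6 * sp[sp > 0].min() * rng.standard_normal(coords.shape)
    canon, _ = geometry.canonicalize(Structure3D(coords))
    return canon


def _leapfrog(state: _State, coords: np.ndarray, mom: np.ndarray,
              stepsize: float, n_steps: int):
    ll, grad = state.coord_loglik_grad(coords)
    mom = mom + 0.5 * stepsize * grad
    for step in range(n_steps):
        coords = coords + stepsize * mom
        ll, grad = state.coord_loglik_grad(coords)
        if step < n_steps - 1:
            mom = mom + stepsize * grad
    mom = mom + 0.5 * stepsize * grad
    return coords, mom, ll


def hmc_update(structure: Structure3D, params: ModelParams,
               effects: RandomEffects | None, counts: ContactMatrix,
               covariates: CovariateSet | None, config: MCMCConfig,
               rng: np.random.Generator,
               energy_error_threshold: float = 1000.0
               ) -> tuple[Structure3D, bool]:
    """One HMC trajectory on the coordinates with fixed parameters.

    Draws a Gaussian momentum, runs a leapfrog trajectory of
    ``config.hmc_steps`` steps, and accepts or rejects by the Metropolis
    rule on the joint Hamiltonian, which leaves the coordinate posterior
    invariant.  A trajectory whose energy error exceeds the threshold is
    treated as divergent and rejected.
    """
    cfg = MCMCConfig(**{**config.__dict__, "beta1_init": params.beta1,
                        "beta0": params.beta0,
                        "mode": "trex" if effects is not None else "tpam"})
    state = _State(counts, covariates, cfg, structure.coords, center_x=False)
    state.beta1 = params.beta1
    state.gamma1, state.gamma2 = params.gamma1, params.gamma2
    if effects is not None:
        state.X = np.asarray(effects.X, dtype=float)
        state.U = np.asarray(effects.U, dtype=float)
    coords = state.coords
    mom = rng.standard_normal(coords.shape)
    ll0, _ = state.coord_loglik_grad(coords)
    h0 = -ll0 + 0.5 * np.sum(mom ** 2)
    new_coords, new_mom, ll1 = _leapfrog(state, coords, mom,
                                         config.hmc_stepsize,
                                         config.hmc_steps)
    h1 = -ll1 + 0.5 * np.sum(new_mom ** 2)
    if not np.isfinite(h1) or (h1 - h0) > energy_error_threshold:
        return structure, False
    if np.log(rng.random()) < h0 - h1:
        return Structure3D(new_coords, structure.labels), True
    return structure, False


def fit(counts: ContactMatrix, covariates: CovariateSet | None,
        config: MCMCConfig) -> PosteriorSamples:
    """Run the Metropolis-within-Gibbs sampler.

    Update cycle per iteration: HMC on the coordinates, Metropolis on
    ``beta1`` (and ``gamma1, gamma2`` when covariates are supplied), and
    in tREX mode Metropolis sweeps over the latent effects followed by
    conjugate variance draws.  Step sizes are adapted during burn-in
    only.  Deterministic given ``config.rng_seed``.
    """
    if np.all(counts.counts == 0):
        raise ValueError("all-zero contact matrix: nothing to fit")
    rng = np.random.default_rng(config.rng_seed)
    init = initialize_structure(counts, config.beta1_init,
                                seed=config.rng_seed)
    state = _State(counts, covariates, config, init.coords)
    # calibrate the initial overall scale: match mean log intensity to
    # the mean log count so the chain starts near the right size regime
    target = float(np.mean(np.log(state.y)))
    offset = float(np.mean(state.cm)) + state.beta0
    log_c = ((target - offset) / state.beta1) - float(np.mean(state.logd))
    state.coords = state.coords * np.exp(log_c)
    state.coords = state.coords - state.coords.mean(axis=0)
    state._refresh_distances()
    if config.coord_prior_factor and np.isfinite(config.coord_prior_factor):
        rms = float(np.sqrt(np.mean(np.sum(state.coords ** 2, axis=1))))
        state.tau2 = (config.coord_prior_factor * rms) ** 2
    have_cov = covariates is not None and config.estimate_gamma

    stepsize = config.hmc_stepsize
    s_b1, s_g, s_x, s_u = (config.scale_beta1, config.scale_gamma,
                           config.scale_x, config.scale_u)
    s_sc = config.scale_expand
    pr_b1 = config.prior_sd_beta1
    pr_g = config.prior_sd_gamma
    a0, b0 = config.prior_ig_shape, config.prior_ig_scale

    n_keep = (config.n_iter - config.burn_in + config.thin - 1) // config.thin
    k_coords = np.empty((n_keep, state.n, 3))
    k_beta1 = np.empty(n_keep)
    k_g1 = np.empty(n_keep)
    k_g2 = np.empty(n_keep)
    k_s2x = np.empty(n_keep)
    k_s2u = np.empty(n_keep)
    k_ll = np.empty(n_keep)

    acc = {"coords": 0, "beta1": 0, "gamma": 0, "x": 0, "u": 0, "scale": 0}
    tries = {"coords": 0, "beta1": 0, "gamma": 0, "x": 0, "u": 0, "scale": 0}
    win_acc = win_try = 0
    kept = 0

    for it in range(config.n_iter):
        adapting = config.adapt and it < config.burn_in

        # --- HMC on coordinates ---------------------------------------
        mom = rng.standard_normal((state.n, 3))
        ll0, _ = state.coord_loglik_grad(state.coords)
        h0 = -ll0 + 0.5 * np.sum(mom ** 2)
        new_coords, new_mom, ll1 = _leapfrog(state, state.coords, mom,
                                             stepsize, config.hmc_steps)
        h1 = -ll1 + 0.5 * np.sum(new_mom ** 2)
        tries["coords"] += 1
        win_try += 1
        ok = np.isfinite(h1) and np.log(rng.random()) < h0 - h1
        if ok:
            state.coords = new_coords
            state._refresh_distances()
            acc["coords"] += 1
            win_acc += 1
        if adapting and win_try == 25:
            rate = win_acc / win_try
            stepsize *= float(np.exp(0.5 * (rate - 0.7)))
            win_acc = win_try = 0

        # --- global scale move on the structure -----------------------
        # The overall size of the structure is a slow, nearly flat
        # direction for HMC (it trades off against beta1 and the
        # quasi-constant covariate terms), so it gets its own
        # multiplicative Metropolis move with the c^(3n) volume Jacobian.
        for _ in range(2):
            log_c = s_sc * rng.standard_normal()
            delta = (np.sum(_trunc_terms(state.y,
                                         state.loglam(logd=state.logd + log_c))
                            - _trunc_terms(state.y, state.loglam()))
                     + 3.0 * state.n * log_c)
            if state.tau2 is not None:
                delta -= ((np.exp(2.0 * log_c) - 1.0)
                          * 0.5 * np.sum(state.coords ** 2) / state.tau2)
            tries["scale"] += 1
            if np.log(rng.random()) < delta:
                state.coords = state.coords * np.exp(log_c)
                state.logd = state.logd + log_c
                acc["scale"] += 1
                if adapting:
                    s_sc *= 1.02
            elif adapting:
                s_sc *= 0.99

        # --- beta1 via RW on log(-beta1) ------------------------------
        phi = np.log(-state.beta1)
        phi_new = phi + s_b1 * rng.standard_normal()
        b1_new = -np.exp(phi_new)
        cur = (state.loglik() - state.beta1 ** 2 / (2 * pr_b1 ** 2) + phi)
        new = (state.loglik(beta1=b1_new) - b1_new ** 2 / (2 * pr_b1 ** 2)
               + phi_new)
        tries["beta1"] += 1
        if np.log(rng.random()) < new - cur:
            state.beta1 = b1_new
            acc["beta1"] += 1
            if adapting:
                s_b1 *= 1.02
        elif adapting:
            s_b1 *= 0.98

        # --- coupled (beta1, scale) ridge move ------------------------
        # beta1 trades off against the overall structure scale along a
        # long posterior ridge; a plain random walk on beta1 crawls
        # along it.  This move changes beta1 and applies the global
        # rescale that keeps the mean log-intensity fixed (the map is an
        # involution; its Jacobian is 3n*log c - delta).
        delta = s_b1 * rng.standard_normal()
        phi = np.log(-state.beta1)
        b1_new = -np.exp(phi + delta)
        m_logd = float(np.mean(state.logd))
        log_c = m_logd * (state.beta1 - b1_new) / b1_new
        new = (state.loglik(beta1=b1_new, logd=state.logd + log_c)
               - b1_new ** 2 / (2 * pr_b1 ** 2))
        cur = state.loglik() - state.beta1 ** 2 / (2 * pr_b1 ** 2)
        jac = 3.0 * state.n * log_c - delta
        if state.tau2 is not None:
            jac -= ((np.exp(2.0 * log_c) - 1.0)
                    * 0.5 * np.sum(state.coords ** 2) / state.tau2)
        if np.log(rng.random()) < new - cur + jac:
            state.beta1 = b1_new
            state.coords = state.coords * np.exp(log_c)
            state.logd = state.logd + log_c

        # --- gamma1, gamma2 -------------------------------------------
        if have_cov:
            for name, cov_vec in (("gamma1", state.cl), ("gamma2", state.cg)):
                g_cur = getattr(state, name)
                g_new = g_cur + s_g * rng.standard_normal()
                delta_ll = float(np.sum(
                    _trunc_terms(state.y, state.loglam(**{name: g_new}))
                    - _trunc_terms(state.y, state.loglam())))
                delta_pr = (g_cur ** 2 - g_new ** 2) / (2 * pr_g ** 2)
                tries["gamma"] += 1
                if np.log(rng.random()) < delta_ll + delta_pr:
                    setattr(state, name, g_new)
                    acc["gamma"] += 1
                    if adapting:
                        s_g *= 1.01
                elif adapting:
                    s_g *= 0.99

        # --- latent effects and variances (tREX only) -----------------
        # latents are held at zero for the first half of burn-in so the
        # structure first converges against the bare likelihood;
        # otherwise the variances inflate to absorb the misfit of the
        # initial structure and the flattened likelihood traps the
        # chain in a poor fold
        latent_start = int(config.latent_warmup_frac * config.burn_in)
        if state.trex and it == latent_start:
            # initialize the locus effects from the least-squares
            # solution of the current log residuals so X and U do not
            # start in competition for the same signal
            resid = np.log(np.maximum(state.y, 0.5)) - state.loglam()
            a = np.zeros((state.m, state.n))
            a[np.arange(state.m), state.rows] = 1.0
            a[np.arange(state.m), state.cols] = 1.0
            xhat, *_ = np.linalg.lstsq(a, resid, rcond=None)
            state.X = xhat - xhat.mean()
            state.sigma2_x = max(float(np.var(state.X)), 1e-4)
        if state.trex and it >= latent_start:
            ll_pairs = state.loglam()
            terms = _trunc_terms(state.y, ll_pairs)
            # per-locus X_i sweep; with the sum-to-zero parameterization
            # a move of X_i shifts every pair's W by -2*dx/n and the
            # pairs incident to i by an additional +dx
            x_acc = 0
            shift = -2.0 / state.n
            for i in range(state.n):
                dx = s_x * rng.standard_normal()
                dw = np.full(state.m, shift * dx)
                dw[state.incident[i]] += dx
                new_ll = ll_pairs + dw
                new_terms = _trunc_terms(state.y, new_ll)
                x_new = state.X[i] + dx
                d_prior = (state.X[i] ** 2 - x_new ** 2) / (2 * state.sigma2_x)
                if np.log(rng.random()) < (np.sum(new_terms - terms)
                                           + d_prior):
                    state.X[i] = x_new
                    ll_pairs = new_ll
                    terms = new_terms
                    x_acc += 1
            acc["x"] += x_acc
            tries["x"] += state.n
            if adapting:
                s_x *= float(np.exp(0.2 * (x_acc / state.n - 0.44)))

            # all-pair U update (terms are independent across pairs)
            du = s_u * rng.standard_normal(state.m)
            u_new = state.U + du
            new_terms = _trunc_terms(state.y, ll_pairs + du)
            d_prior = (state.U ** 2 - u_new ** 2) / (2 * state.sigma2_u)
            accept = (np.log(rng.random(state.m))
                      < new_terms - terms + d_prior)
            state.U[accept] = u_new[accept]
            acc["u"] += int(np.sum(accept))
            tries["u"] += state.m
            if adapting:
                s_u *= float(np.exp(0.2 * (np.mean(accept) - 0.44)))

            # exact Gibbs rebalancing between X_i and the pair effects:
            # moving along (X_i + t, U - b*t) leaves every W_ij (hence
            # the likelihood) unchanged, so t has a Gaussian conditional
            # determined by the priors alone; without this move the
            # confounded X/U direction mixes pathologically slowly
            for i in range(state.n):
                b = np.full(state.m, shift)
                b[state.incident[i]] += 1.0
                prec = 1.0 / state.sigma2_x + np.dot(b, b) / state.sigma2_u
                mean_t = ((np.dot(state.U, b) / state.sigma2_u
                           - state.X[i] / state.sigma2_x) / prec)
                t = mean_t + rng.standard_normal() / np.sqrt(prec)
                state.X[i] += t
                state.U -= b * t

            # conjugate inverse-gamma draws for the variances
            state.sigma2_x = 1.0 / rng.gamma(
                a0 + 0.5 * state.n, 1.0 / (b0 + 0.5 * np.sum(state.X ** 2)))
            state.sigma2_u = 1.0 / rng.gamma(
                a0 + 0.5 * state.m, 1.0 / (b0 + 0.5 * np.sum(state.U ** 2)))

        # --- store ----------------------------------------------------
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            canon, _ = geometry.canonicalize(Structure3D(state.coords))
            k_coords[kept] = canon.coords
            k_beta1[kept] = state.beta1
            k_g1[kept] = state.gamma1
            k_g2[kept] = state.gamma2
            k_s2x[kept] = state.sigma2_x
            k_s2u[kept] = state.sigma2_u
            k_ll[kept] = state.loglik()
            kept += 1

    rates = {k: acc[k] / tries[k] for k in acc if tries[k] > 0}
    rates["hmc_stepsize_final"] = stepsize
    return PosteriorSamples(coords=k_coords[:kept], beta1=k_beta1[:kept],
                            gamma1=k_g1[:kept], gamma2=k_g2[:kept],
                            sigma2_x=k_s2x[:kept], sigma2_u=k_s2u[:kept],
                            loglik=k_ll[:kept], accept_rates=rates,
                            config=config)


def point_estimate(samples: PosteriorSamples,
                   mode: str = "mean") -> Structure3D:
    """Posterior point estimate of the structure.

    ``mode="mean"``: coordinate-wise mean of the canonicalized draws,
    re-canonicalized.  ``mode="max_loglik"``: the single retained draw
    with the highest log-likelihood.
    """
    if samples.n_draws == 0:
        raise ValueError("no retained draws")
    if mode == "mean":
        est = samples.coords.mean(axis=0)
    elif mode == "max_loglik":
        est = samples.coords[int(np.argmax(samples.loglik))]
    else:
        raise ValueError("mode must be 'mean' or 'max_loglik'")
    canon, _ = geometry.canonicalize(Structure3D(est))
    return canon


def posterior_distance_summary(samples: PosteriorSamples,
                               pairs,
                               quantiles=(0.025, 0.5, 0.975)):
    """Per-pair posterior summaries of the Euclidean distance.

    Returns a DataFrame with one row per requested ``(i, j)`` pair and
    the median plus the requested quantiles of ``d_ij`` across draws.
    The medians feed the distance standardization used to compare
    against imaging (FISH) measurements.
    """
    import pandas as pd

    n = samples.n_loci
    recs = []
    for (i, j) in pairs:
        if not (0 <= i < n and 0 <= j < n and i != j):
            raise ValueError(f"invalid pair ({i}, {j})")
        d = np.linalg.norm(samples.coords[:, i, :] - samples.coords[:, j, :],
                           axis=1)
        rec = {"i": i, "j": j, "median": float(np.median(d))}
        for q in quantiles:
            rec[f"q{q:g}"] = float(np.quantile(d, q))
        recs.append(rec)
    return pd.DataFrame(recs)
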