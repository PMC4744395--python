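# Methods

## The model

`trex3d` reconstructs a 3D chromatin structure from a Hi-C contact
matrix. Loci `i = 1..n` have unknown coordinates
`p_i = (x_i, y_i, z_i)`; the contact count `y_ij` between loci `i < j`
is modelled by a **zero-truncated Poisson** whose log-intensity is
log-linear in the Euclidean distance `d_ij`:

    log λ_ij = β0 + β1 log d_ij
             + γ1 log(z_l,i z_l,j) + γ2 log(z_g,i z_g,j)
             + log(z_m,i z_m,j) + W_ij ,        β1 < 0

with per-locus bias covariates `z` (fragment length, GC content,
mappability; the mappability coefficient is fixed at 1 — it can be set
to another value in `ModelParams` but is not sampled) and a pair
random effect

    W_ij = X_i + X_j + U_ij ,
    X_i ~ N(0, σx²)  i.i.d.,   U_ij ~ N(0, σu²)  i.i.d.

Only pairs with `y_ij > 0` enter the likelihood

    ℓ = Σ_{y_ij>0} [ y_ij log λ_ij − log(e^{λ_ij} − 1) − log y_ij! ] ,

so sparse high-resolution matrices get cheaper, not harder, and the
model never has to explain individual zeros. With `σx² = σu² = 0` the
model is the truncated Poisson architecture model (tPAM); with the
random effects it is tREX. The random-effect layer buys two things the
bare truncated Poisson cannot express: overdispersion (the truncated
Poisson's variance is strictly below its mean) and positive correlation
between the intensities of two pairs sharing a locus.

`U_ij` is instantiated only on the nonzero-count pairs: zero pairs
never enter the likelihood, so latents on them would be sampled from
their prior to no effect.

### Identifiability

The likelihood sees only pairwise distances, so the structure is
defined up to translation, rotation, reflection and — because `β0` is
fixed rather than estimated (default 3) — an overall scale. Stored
posterior draws and point estimates are mapped to a canonical frame
fixed by four conditions on anchor loci 1, 2, 3, n: `p_1 = 0`;
`p_2` in the xz-plane with `p_2^z > 0`; `p_3^y > 0` (fixes chirality);
`p_n` on the positive x-axis.

Two further parameterization choices are needed to make the *sampled*
model well behaved; both are equivalent to redefining the arbitrary
fixed intercept and change nothing about the reported structures:

* **Centered covariate terms.** The study covariates have narrow
  ranges, so `γ·log(z_i z_j)` is nearly constant across pairs and acts
  as a free intercept; with `β0` fixed that silently destroys the
  scale identification (the posterior then drifts to arbitrarily large
  structures with `γ` compensating). The analysis model centers the
  three log-covariate pair terms to mean zero.
* **Sum-to-zero locus effects.** The grand mean of `X` is another free
  intercept; the likelihood uses `X_i − X̄`.

### Coordinate prior

A completely flat coordinate prior makes the tREX posterior improper:
a power-stretch of the configuration (`d → d^t`, `β1 → β1/t`) can be
absorbed by the pair latents `U` at finite prior cost while the
coordinate volume factor grows without bound; chains drift to
`β1 → 0⁻` and astronomically large structures. The coordinates
therefore get an isotropic Gaussian prior centered at the origin whose
SD is `coord_prior_factor` (default 1.5) times the RMS radius of the
(data-calibrated) initialization. This is weak at the scale of local
rearrangements but closes the stretch escape. The factor trades a
small shape shrinkage against ridge leakage; 1.5 gave the best
structure recovery across the simulation grid and is exposed in
`MCMCConfig`.

## Inference

Metropolis-within-Gibbs, fully seeded and bit-reproducible:

1. **Coordinates — HMC.** Leapfrog trajectories (default 10 steps) on
   the joint log-posterior of all `3n` coordinates, using the analytic
   gradient `dℓ/dlog λ = y − λ/(1 − e^{−λ})` chained through
   `∂log λ/∂d = β1/d`. The stepsize is tuned during burn-in to a
   ~70 % acceptance rate.
2. **Global scale.** A multiplicative Metropolis move `ω → cω` with the
   `c^{3n}` volume Jacobian; the scale direction is nearly flat for
   HMC and mixes pathologically slowly without it.
3. **β1.** A random-walk step on `log(−β1)` (enforcing negativity),
   plus a *coupled* (β1, scale) move that applies the compensating
   global rescale keeping the mean log-intensity fixed — an exact
   involution with Jacobian `3n log c − δ`. β1 and the structure scale
   lie on a long ridge; the coupled move is what makes β1 chains
   stationary within ~2k iterations instead of drifting for tens of
   thousands.
4. **γ1, γ2.** Scalar random-walk Metropolis (skipped when no
   covariate table is supplied).
5. **Latents (tREX only).** Per-locus Metropolis on `X_i`; a
   vectorized all-pair Metropolis on `U` (the per-pair terms do not
   interact); then an *exact Gibbs rebalancing* move per locus along
   the likelihood-invariant direction `(X_i + t, U − b t)`, whose
   conditional is Gaussian in the priors alone. X and U compete for
   the same residual and without this move the confounded direction
   mixes far too slowly. Latents are held at zero for the first half
   of burn-in (`latent_warmup_frac`), letting the structure converge
   against the bare likelihood first — otherwise the variances inflate
   to absorb the initial misfit and trap the chain in a poor fold.
   When they switch on, `X` is initialized from the least-squares
   solution of the current log-residuals.
6. **Variances.** Conjugate inverse-gamma draws,
   `σ² ~ InvGamma(2, 0.1)` a priori.

Priors elsewhere: `β1 ~ N(0, 10²)` truncated negative,
`γ ~ N(0, 10²)`. Proposal scales adapt during burn-in only. Defaults:
15 000 iterations, 5 000 burn-in, thinning 1.

**Initialization** is classical metric MDS on surrogate distances
`(y_ij + 1)^{1/β1}`, with zero pairs imputed by shortest paths over the
nonzero-pair graph (disconnected components are bridged with a large
distance and a warning), followed by a one-step global rescale matching
the mean log-intensity to the mean log-count.

**Point estimate**: coordinate-wise mean of the canonicalized retained
draws, re-canonicalized (a max-likelihood-draw option exists but is
noticeably worse — a single draw carries the full posterior wobble).

## Evaluation

* **Scale correction**: `α̂ = Σ d·d̂ / Σ d̂²`, the least-squares match
  of the estimated to the true distance matrix.
* **RMSD**: `sqrt((1/n) Σ_i ‖ℑ(α̂ p̂_i) − ℑ(p_i)‖²)` with ℑ the
  canonical isometry; plots conventionally use `√n·RMSD`.
* **Correlation**: Pearson correlation of the `3n` aligned coordinate
  values, after the same scale-and-canonicalize alignment as RMSD (an
  unaligned coordinate correlation would be meaningless under
  rotation).
* **TAD preservation**: the average silhouette width of the true
  two-domain labeling computed on the estimate, divided by the same
  quantity on the truth. Silhouette is isometry-invariant, so no
  alignment is needed.
* **Method comparison**: paired one-sided Wilcoxon signed-rank tests
  across replicates per resolution level (exact null for n ≤ 25, ties
  by mid-rank permutation; normal approximation with continuity
  correction otherwise). One-sided in the baseline's favor by default,
  configurable to two-sided.
* **Distance standardization**: posterior median distances divided by
  a reference pair's median, making them comparable to unit-free
  imaging (FISH) distances.

## Synthetic study design

Data resolution is emulated by zero-inflation: each upper-triangle
entry is zero with probability `π ∈ {0, 0.1, 0.2, 0.3, 0.6}` (matching
the empirical zero shares of 1 Mb … 10 Kb intra-chromosomal data) and
otherwise Poisson with the model intensity. Generating parameters:
`β0 = 3`, `β1 = −0.434`, `(γ1, γ2) ∈ {(0.3, 0.3), (0.05, 0.25),
(0.05, −0.25)}`; covariates `z_l ~ U(0.2, 0.3)`, `z_g ~ U(0.4, 0.5)`,
`z_m ~ U(0.9, 1)`. The NRE ("no random effect") model stops there; the
ST model adds `W_ij = X_i + X_j + U_ij` with `X_i` Azzalini skew-t
`ST(0, scale 0.3, shape 1, df 10)` and `U_ij ~ N(0, 0.1²)` (`σ_u` is a
package default — small relative to the skew-t scale so locus-level
effects dominate). The full factorial grid is 2 models × 3 coefficient
sets × 5 zero levels = 30 settings, default 50 replicates each.

The **gold-standard structure** is synthetic: 43 loci in two
consecutive domains (22/21) built as smooth 3D random walks, the
second domain displaced along a random direction until the labeling's
average silhouette width exceeds 0.55 (with a floor of 3× the larger
within-domain radius). The overall scale is set so the maximum
pairwise distance is 0.4, a one-time calibration making every pair's
intensity ≥ ~5 at the default parameters, i.e. a zero-free matrix at
`π = 0`.

### What the generator does and does not emulate

It reproduces the count model, bias covariates, overdispersion,
shared-locus correlation and the zero-inflation ladder. It does **not**
reproduce a real chromatin fold: the generating structure in the
original study was itself estimated from real Hi-C data and is not
public, so ours is a documented stand-in with the same locus count and
the two-domain property. This matters quantitatively: with the
synthetic fold and the `β0 = 3` intensity ceiling, inter-domain pairs
carry weak information and even the *maximum-likelihood* structure
under the exact generating likelihood reaches only ~0.7 aligned
correlation on ST data (~0.83 on NRE at 60 % zeros) — so passing or
failing the >90 % benchmarks here reflects the synthetic conditions,
not only the method. tREX's latents recover part of the gap (its
estimates beat the tPAM-likelihood optimum on ST data), reproducing
the study's qualitative ordering.

A second caveat: the joint ML of (structure, β1) at `n = 43` carries a
substantial incidental-parameters bias (~122 coordinate nuisances
against ≤ 903 observations pull β1 from −0.434 to ≈ −0.67 even when
optimization starts at the truth). Posterior means land between the
MLE and the truth; frequentist-calibrated credible intervals for β1
cannot be expected at this problem size.

## Numerical choices

* `log(e^λ − 1)` computed as `λ + log1p(−e^{−λ})`; λ floored at 1e−12.
* Canonicalization tolerance 1e−10; degenerate anchor configurations
  raise with the violated condition named.
* Counts above 2^53 are rejected by the readers (float-exactness
  guard); missing covariates mean all `z ≡ 1`.
* Benchmark problem sizes: the acceptance script uses 5 replicates per
  level and 6 000-iteration chains (3 000 burn-in); the test suite uses
  4 000/2 000. These are the package's scaled-down study sizes; the
  full-scale defaults (50 replicates, 15 000 iterations) are one flag
  away in `trex3d study`.

## Known limitations

* Single-chain inference; no R̂/multi-chain machinery beyond a
  Geweke-style stationarity check in the tests.
* The structure posterior is multimodal over folds at high zero
  inflation; replicate-to-replicate variation of the estimate quality
  is real and substantial there.
* No genomic-coordinate awareness (loci are opaque ordered bins), no
  binary `.hic`/`.cool` readers, no read-level simulation.
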