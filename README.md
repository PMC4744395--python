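# trex3d

Bayesian inference of 3D chromatin structure from Hi-C contact
matrices, for computational biologists studying genome architecture
and for methodologists benchmarking structure-inference methods across
data resolutions.

A Hi-C experiment counts pairwise spatial contacts between genomic
loci. `trex3d` models the count `y_ij` between loci `i` and `j` with a
**zero-truncated Poisson** whose intensity is log-linear in the
unknown 3D distance,

```
log λ_ij = β0 + β1 log d_ij + γ1 log(z_l,i z_l,j)
         + γ2 log(z_g,i z_g,j) + log(z_m,i z_m,j) + W_ij ,   β1 < 0
```

where the `z` are per-locus bias covariates (fragment length, GC,
mappability) and `W_ij = X_i + X_j + U_ij` is a Gaussian random effect
capturing overdispersion and the correlation between pairs sharing a
locus (**tREX**; with the random-effect variances pinned to zero the
model is **tPAM**). Only nonzero counts enter the likelihood, which
makes the method robust to the zero excess of high-resolution
matrices. Coordinates are sampled by Hamiltonian Monte Carlo inside a
Metropolis-within-Gibbs cycle; estimates are reported in a canonical
frame (anchor loci pinned) that removes the rotation/translation/
reflection/scale invariance. A zero-inflated Poisson simulator
reproduces the method's in-silico benchmark: a 43-locus two-domain
gold structure, two generating models (NRE without and ST with skew-t
random effects), and zero levels {0, 0.1, 0.2, 0.3, 0.6} standing in
for 1 Mb … 10 Kb resolution. See `docs/methods.md` for the full model
and design account.

## Worked example

```python
import numpy as np
from trex3d.simulator import make_gold_structure, simulate_dataset, SimulationConfig
from trex3d.inference import MCMCConfig, fit, point_estimate
from trex3d import evaluation

gold = make_gold_structure(n=43, seed=1)          # two-TAD gold structure
cfg = SimulationConfig(model="NRE", pi=0.3)       # 30 % zeros ≈ 20 Kb resolution
counts, covariates = simulate_dataset(gold, cfg, seed=7)

mcmc = MCMCConfig(n_iter=6000, burn_in=3000, mode="trex", rng_seed=7)
samples = fit(counts, covariates, mcmc)
estimate = point_estimate(samples)

print({k: round(v, 3) for k, v in
       evaluation.evaluate_structure(estimate, gold).items()})
print("beta1 posterior mean:", round(float(np.mean(samples.beta1)), 3))
```

Output from this exact script:

```
{'rmsd': 0.084, 'sqrt_n_rmsd': 0.554, 'correlation': 0.912, 'silhouette_ratio': 1.258}
beta1 posterior mean: -0.524
```

`rmsd` is the root-mean-square coordinate deviation after least-squares
scale correction and canonical alignment (the structure's diameter is
0.4, so 0.08 is a ~20 % relative error); `correlation` is the Pearson
correlation of the aligned coordinates (0.91 = the fold is recovered);
`silhouette_ratio` compares the spatial separation of the two true
domains in the estimate against the truth (≈1 = TAD structure
preserved, here slightly sharpened). The β1 posterior mean sits below
the generating −0.434; at n = 43 the many free coordinates bias the
slope (see the methods note).

The same pipeline is scriptable from the shell:

```
trex3d simulate --model st --pi 0.6 --seed 7 --out-dir sim/
trex3d fit --counts sim/contacts_rep0.tsv --covariates sim/covariates_rep0.csv \
           --mode trex --seed 1 --out-dir fit/
trex3d evaluate --estimate fit/structure_estimate.csv --truth sim/gold_structure.csv
trex3d study --replicates 2 --n-iter 2500 --burn-in 1000 --out-dir study/
```

`fit` writes the point estimate (`xyz` CSV and a PDB-like file for
molecular viewers), posterior parameter summaries, a samples container,
and a config echo for bit-exact re-runs.

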