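"""Probability model for Hi-C contact counts.

The model places ``n`` genomic loci in 3D space and links the observed
contact count ``y_ij`` between loci ``i`` and ``j`` to their Euclidean
distance ``d_ij`` through a log-linear intensity,

    log lambda_ij = beta0 + beta1*log d_ij
                    + gamma1*log(z_l_i z_l_j) + gamma2*log(z_g_i z_g_j)
                    + log(z_m_i z_m_j) + W_ij,

with ``beta1 < 0`` (closer loci interact more), per-locus bias covariates
``z`` (fragment length, GC content, mappability; the mappability
coefficient is fixed at 1 by default), and an optional random effect
``W_ij = X_i + X_j + U_ij`` capturing overdispersion and the correlation
between pairs that share a locus.  Counts are modelled by a
*zero-truncated* Poisson: only pairs with ``y_ij > 0`` enter the
likelihood, which makes the model robust to the excess zeros of
high-resolution contact matrices.

With ``W_ij`` present the model is called tREX; with the random-effect
variances pinned at zero it reduces to the truncated Poisson
architecture model (tPAM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

__all__ = [
    "Structure3D",
    "ContactMatrix",
    "CovariateSet",
    "ModelParams",
    "RandomEffects",
    "nonzero_pairs",
    "pairwise_distances",
    "log_intensity",
    "truncated_poisson_loglik",
    "truncated_poisson_moments",
    "loglik_gradient",
]


@dataclass
class Structure3D:
    """An ordered set of loci with 3D coordinates (arbitrary units).

    Parameters
    ----------
    coords
        Array of shape ``(n, 3)``; row ``i`` is the position of locus ``i``.
    labels
        Optional per-locus domain labels (e.g. TAD membership), length ``n``.
    """

    coords: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if self.coords.shape[0] < 4:
            raise ValueError("need at least 4 loci (anchors 1, 2, 3, n)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.coords.shape[0]:
                raise ValueError("labels length must match number of loci")

    @property
    def n_loci(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Structure3D":
        return Structure3D(
            self.coords.copy(),
            None if self.labels is None else self.labels.copy(),
        )


@dataclass
class ContactMatrix:
    """Symmetric matrix of non-negative integer contact counts.

    Only the upper triangle (``i < j``) carries information; the diagonal
    is ignored and forced to zero.
    """

    counts: np.ndarray
    loci_ids: Sequence[str] | None = None
    resolution_tag: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValueError("counts must be integers")
            c = np.round(c).astype(np.int64)
        else:
            c = c.astype(np.int64)
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if not np.array_equal(c, c.T):
            raise ValueError("contact matrix must be symmetric")
        np.fill_diagonal(c, 0)
        self.counts = c
        if self.loci_ids is not None and len(self.loci_ids) != c.shape[0]:
            raise ValueError("loci_ids length must match matrix size")

    @property
    def n_loci(self) -> int:
        return self.counts.shape[0]


@dataclass
class CovariateSet:
    """Per-locus bias covariates entering the intensity as pair products.

    All three vectors must be strictly positive because the model takes
    ``log(z_i z_j)`` for each pair.
    """

    z_l: np.ndarray  # fragment length
    z_g: np.ndarray  # GC content
    z_m: np.ndarray  # mappability

    def __post_init__(self) -> None:
        for name in ("z_l", "z_g", "z_m"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim != 1:
                raise ValueError(f"{name} must be a 1D vector")
            if np.any(v <= 0) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be strictly positive and finite")
            setattr(self, name, v)
        n = self.z_l.shape[0]
        if self.z_g.shape[0] != n or self.z_m.shape[0] != n:
            raise ValueError("covariate vectors must have equal length")

    @property
    def n_loci(self) -> int:
        return self.z_l.shape[0]

    @classmethod
    def ones(cls, n: int) -> "CovariateSet":
        """Unit covariates: all bias terms vanish from the intensity."""
        one = np.ones(n)
        return cls(one, one.copy(), one.copy())


@dataclass
class ModelParams:
    """Coefficients and random-effect variances of the intensity model.

    ``beta0`` is held fixed (it only sets the overall scale of the
    structure); ``beta1`` must be strictly negative.  ``sigma2_x`` and
    ``sigma2_u`` are the variances of the locus-level and pair-level
    random effects; both zero corresponds to tPAM.
    """

    beta0: float = 3.0
    beta1: float = -1.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    gamma_m: float = 1.0  # mappability coefficient, fixed at 1 by convention
    sigma2_x: float = 0.0
    sigma2_u: float = 0.0

    def __post_init__(self) -> None:
        if not self.beta1 < 0:
            raise ValueError("beta1 must be strictly negative")
        if self.sigma2_x < 0 or self.sigma2_u < 0:
            raise ValueError("random-effect variances must be >= 0")

    @property
    def is_tpam(self) -> bool:
        return self.sigma2_x == 0.0 and self.sigma2_u == 0.0


@dataclass
class RandomEffects:
    """Latent random effects: locus-level ``X_i`` and pair-level ``U_ij``.

    ``U`` is stored only for the pairs that enter the likelihood (the
    nonzero-count index set), aligned with the ``(rows, cols)`` arrays of
    :func:`nonzero_pairs`.
    """

    X: np.ndarray
    U: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.U = np.asarray(self.U, dtype=float)

    def pair_effects(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """W_ij = X_i + X_j + U_ij on the given pair index arrays."""
        return self.X[rows] + self.X[cols] + self.U


def nonzero_pairs(counts: ContactMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle index arrays ``(rows, cols)`` of nonzero counts."""
    iu, ju = np.triu_indices(counts.n_loci, k=1)
    mask = counts.counts[iu, ju] != 0
    return iu[mask], ju[mask]


def pairwise_distances(structure: Structure3D) -> np.ndarray:
    """Full symmetric matrix of Euclidean distances between loci.

    Raises
    ------
    ValueError
        If any two distinct loci coincide (their log-distance would be
        undefined downstream).
    """
    d = squareform(pdist(structure.coords))
    n = structure.n_loci
    off = d[np.triu_indices(n, k=1)]
    if np.any(off == 0):
        raise ValueError("degenerate structure: coincident loci (d_ij = 0)")
    return d


def _pair_log_covariates(covariates: CovariateSet,
                         rows: np.ndarray, cols: np.ndarray,
                         gamma1: float, gamma2: float,
                         gamma_m: float) -> np.ndarray:
    lz_l = np.log(covariates.z_l)
    lz_g = np.log(covariates.z_g)
    lz_m = np.log(covariates.z_m)
    return (gamma1 * (lz_l[rows] + lz_l[cols])
            + gamma2 * (lz_g[rows] + lz_g[cols])
            + gamma_m * (lz_m[rows] + lz_m[cols]))


def log_intensity(params: ModelParams,
                  distances: np.ndarray,
                  covariates: CovariateSet | None = None,
                  effects: RandomEffects | None = None,
                  rows: np.ndarray | None = None,
                  cols: np.ndarray | None = None) -> np.ndarray:
    """Log intensity ``log lambda_ij`` of the contact model.

    If ``rows``/``cols`` are given, returns a vector over those pairs
    (the representation used in the likelihood); otherwise returns the
    full symmetric matrix with an unused zero diagonal, in which case
    ``effects`` must be ``None`` (pair-level effects are defined only on
    the likelihood's index set).
    """
    distances = np.asarray(distances, dtype=float)
    n = distances.shape[0]
    full = rows is None
    if full:
        if effects is not None:
            raise ValueError("full-matrix form does not accept random effects")
        rows, cols = np.triu_indices(n, k=1)
    d = distances[rows, cols]
    if np.any(d <= 0):
        raise ValueError("distances must be strictly positive off-diagonal")
    ll = params.beta0 + params.beta1 * np.log(d)
    if covariates is not None:
        ll = ll + _pair_log_covariates(covariates, rows, cols,
                                       params.gamma1, params.gamma2,
                                       params.gamma_m)
    if effects is not None:
        ll = ll + effects.pair_effects(rows, cols)
    if full:
        out = np.zeros((n, n))
        out[rows, cols] = ll
        out[cols, rows] = ll
        return out
    return ll


def _log_expm1(lam: np.ndarray) -> np.ndarray:
    # log(e^lam - 1) = lam + log(1 - e^-lam), stable for large lam
    lam = np.maximum(lam, 1e-12)
    return lam + np.log1p(-np.exp(-lam))


def truncated_poisson_loglik(counts: ContactMatrix,
                             log_lambda: np.ndarray,
                             rows: np.ndarray | None = None,
                             cols: np.ndarray | None = None) -> float:
    """Zero-truncated Poisson log-likelihood over nonzero pairs.

    ``sum_{(i,j): y_ij > 0} [ y_ij*log lambda_ij - log(e^lambda_ij - 1)
    - log(y_ij!) ]`` — the exact sum of zero-truncated log-pmfs.  The
    ``log(y!)`` normalization is constant in the parameters (it is
    usually dropped from the sampler's kernel) but is included so the
    value is a genuine log-likelihood.

    ``log_lambda`` may be the full matrix or, with ``rows``/``cols``, a
    vector over exactly those pairs.  Pairs with zero counts contribute
    nothing (truncation).
    """
    if rows is None:
        rows, cols = nonzero_pairs(counts)
        ll = np.asarray(log_lambda)[rows, cols]
    else:
        ll = np.asarray(log_lambda, dtype=float)
        mask = counts.counts[rows, cols] != 0
        rows, cols, ll = rows[mask], cols[mask], ll[mask]
    if not np.all(np.isfinite(ll)):
        raise ValueError("log intensities must be finite on nonzero pairs")
    y = counts.counts[rows, cols]
    lam = np.exp(ll)
    return float(np.sum(y * ll - _log_expm1(lam) - gammaln(y + 1.0)))


def truncated_poisson_moments(lam: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of the zero-truncated Poisson.

    mean = lam / (1 - e^-lam); var = mean * (1 + lam - mean).
    The mean always exceeds the variance (the truncated distribution is
    underdispersed), which is why a random-effect layer is needed to
    accommodate overdispersed counts.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lambda must be strictly positive")
    mean = lam / (-np.expm1(-lam))
    var = mean * (1.0 + lam - mean)
    if lam.ndim == 0:
        return float(mean), float(var)
    return mean, var


def loglik_gradient(params: ModelParams,
                    structure: Structure3D,
                    covariates: CovariateSet | None,
                    effects: RandomEffects | None,
                    counts: ContactMatrix,
                    rows: np.ndarray | None = None,
                    cols: np.ndarray | None = None,
                    with_params: bool = False):
    """Analytic gradient of the truncated log-likelihood.

    Returns the ``(n, 3)`` gradient with respect to the coordinates; with
    ``with_params=True`` also returns ``(d/dbeta1, d/dgamma1, d/dgamma2)``.

    Uses ``dL/dlog lambda = y - lambda/(1 - e^-lambda)`` chained through
    ``dlog lambda/dd_ij = beta1/d_ij`` and ``dd_ij/dp_i = (p_i-p_j)/d_ij``.
    ``rows``/``cols`` must index the nonzero pairs when ``effects`` is
    given (its ``U`` is aligned with them).
    """
    if rows is None:
        rows, cols = nonzero_pairs(counts)
    n = structure.n_loci
    p = structure.coords
    diff = p[rows] - p[cols]
    d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    if np.any(d <= 0):
        raise ValueError("degenerate structure: coincident loci")
    ll = params.beta0 + params.beta1 * np.log(d)
    if covariates is not None:
        ll = ll + _pair_log_covariates(covariates, rows, cols,
                                       params.gamma1, params.gamma2,
                                       params.gamma_m)
    if effects is not None:
        ll = ll + effects.pair_effects(rows, cols)
    y = counts.counts[rows, cols]
    lam = np.exp(ll)
    g_loglam = y - lam / (-np.expm1(-np.maximum(lam, 1e-12)))

    # d loglik / d p_i, accumulated over pairs containing i
    w = g_loglam * params.beta1 / (d * d)  # per-pair scalar on (p_i - p_j)
    contrib = w[:, None] * diff
    grad = np.zeros((n, 3))
    for k in range(3):
        grad[:, k] = (np.bincount(rows, weights=contrib[:, k], minlength=n)
                      - np.bincount(cols, weights=contrib[:, k], minlength=n))
    if not with_params:
        return grad
    d_beta1 = float(np.sum(g_loglam * np.log(d)))
    if covariates is not None:
        lz_l = np.log(covariates.z_l)
        lz_g = np.log(covariates.z_g)
        d_g1 = float(np.sum(g_loglam * (lz_l[rows] + lz_l[cols])))
        d_g2 = float(np.sum(g_loglam * (lz_g[rows] + lz_g[cols])))
    else:
        d_g1 = d_g2 = 0.0
    return grad, (d_beta1, d_g1, d_g2)
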