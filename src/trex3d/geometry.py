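"""Identifiability canonicalization and structure-comparison metrics.

A 3D embedding inferred from pairwise contact data is only determined up
to translation, rotation, reflection and (because the intercept of the
intensity model is fixed rather than estimated) an overall scale.  The
canonical frame used throughout this package pins that freedom down with
four conditions on anchor loci 1, 2, 3 and n:

* ``p_1 = (0, 0, 0)``
* ``p_2 = (p2x, 0, p2z)`` with ``p2z > 0``
* ``p_3`` has ``p3y > 0``  (fixes chirality / reflection)
* ``p_n = (pnx, 0, 0)`` with ``pnx > 0``

Structures are compared by first estimating a least-squares scale factor
from the two distance matrices, mapping both structures into the
canonical frame, and then computing RMSD or the Pearson correlation of
the aligned coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import Structure3D, pairwise_distances

__all__ = [
    "CanonicalFrame",
    "canonicalize",
    "estimate_scale",
    "rmsd",
    "sqrt_n_rmsd",
    "aligned_correlation",
]

_EPS = 1e-12


@dataclass
class CanonicalFrame:
    """The isometry applied by :func:`canonicalize`.

    ``canonical = R @ (p - t)`` applied row-wise; ``R`` includes any
    reflection.  Invertible via :meth:`inverse_transform`.
    """

    rotation: np.ndarray  # (3, 3), orthogonal (det = +/-1)
    translation: np.ndarray  # (3,)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords) - self.translation) @ self.rotation.T

    def inverse_transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation + self.translation


def _rotation_to_x_axis(v: np.ndarray) -> np.ndarray:
    """Orthogonal rotation R with R @ v = (|v|, 0, 0)."""
    norm = np.linalg.norm(v)
    u = v / norm
    x = np.array([1.0, 0.0, 0.0])
    c = float(u @ x)
    if c > 1.0 - 1e-15:
        return np.eye(3)
    if c < -1.0 + 1e-15:
        # 180 degrees about z
        return np.diag([-1.0, -1.0, 1.0])
    axis = np.cross(u, x)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array([[0.0, -axis[2], axis[1]],
                  [axis[2], 0.0, -axis[0]],
                  [-axis[1], axis[0], 0.0]])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def canonicalize(structure: Structure3D) -> tuple[Structure3D, CanonicalFrame]:
    """Map a structure into the canonical frame (an exact isometry).

    Anchors are loci 1, 2, 3 and n (0-based 0, 1, 2, n-1).  Raises a
    ``ValueError`` naming the violated condition when the anchors are in
    degenerate position.  Idempotent: a canonical structure maps to
    itself (up to floating-point roundoff).
    """
    p = structure.coords
    n = p.shape[0]
    t = p[0].copy()
    q = p - t

    v_n = q[n - 1]
    if np.linalg.norm(v_n) < _EPS:
        raise ValueError("degenerate anchors: locus n coincides with locus 1")
    R1 = _rotation_to_x_axis(v_n)
    q = q @ R1.T

    # rotate about the x-axis to put locus 2 into the xz-plane with z > 0
    y2, z2 = q[1, 1], q[1, 2]
    r = np.hypot(y2, z2)
    if r < _EPS:
        raise ValueError(
            "degenerate anchors: locus 2 lies on the line through loci 1 and n")
    c, s = z2 / r, y2 / r
    R2 = np.array([[1.0, 0.0, 0.0],
                   [0.0, c, -s],
                   [0.0, s, c]])
    q = q @ R2.T

    R = R2 @ R1
    if abs(q[2, 1]) < _EPS:
        raise ValueError(
            "degenerate anchors: locus 3 lies in the plane of loci 1, 2, n")
    if q[2, 1] < 0:
        F = np.diag([1.0, -1.0, 1.0])
        q = q @ F
        R = F @ R

    out = Structure3D(q, None if structure.labels is None
                      else structure.labels.copy())
    return out, CanonicalFrame(rotation=R, translation=t)


def estimate_scale(d_true: np.ndarray, d_est: np.ndarray) -> float:
    """Least-squares scale factor aligning an estimated distance matrix.

    Minimizes ``sum_{i<j} (d_ij - alpha * dhat_ij)^2``; the closed-form
    minimizer is ``sum d*dhat / sum dhat^2`` over the upper triangle.
    """
    d_true = np.asarray(d_true, dtype=float)
    d_est = np.asarray(d_est, dtype=float)
    if d_true.shape != d_est.shape:
        raise ValueError("distance matrices must have matching shapes")
    iu = np.triu_indices(d_true.shape[0], k=1)
    num = float(np.sum(d_true[iu] * d_est[iu]))
    den = float(np.sum(d_est[iu] ** 2))
    if den == 0.0:
        raise ValueError("estimated distances are identically zero")
    return num / den


def _aligned_coords(truth: Structure3D,
                    estimate: Structure3D) -> tuple[np.ndarray, np.ndarray]:
    if truth.n_loci != estimate.n_loci:
        raise ValueError("structures must have the same number of loci")
    alpha = estimate_scale(pairwise_distances(truth),
                           pairwise_distances(estimate))
    scaled = Structure3D(alpha * estimate.coords)
    est_c, _ = canonicalize(scaled)
    tru_c, _ = canonicalize(truth)
    return tru_c.coords, est_c.coords


def rmsd(truth: Structure3D, estimate: Structure3D) -> float:
    """Root mean square deviation after scale and canonical alignment.

    ``sqrt( (1/n) sum_i || canon(alpha*phat_i) - canon(p_i) ||^2 )``.
    Zero iff the estimate is a scaled isometry of the truth.
    """
    tru, est = _aligned_coords(truth, estimate)
    return float(np.sqrt(np.mean(np.sum((est - tru) ** 2, axis=1))))


def sqrt_n_rmsd(truth: Structure3D, estimate: Structure3D) -> float:
    """The plotting convention ``sqrt(n) * RMSD``."""
    return float(np.sqrt(truth.n_loci) * rmsd(truth, estimate))


def aligned_correlation(truth: Structure3D, estimate: Structure3D) -> float:
    """Pearson correlation of coordinates after the RMSD alignment.

    Both structures are scale-corrected and mapped to the canonical
    frame; the correlation is over the ``3n`` concatenated coordinate
    values.  1 for any scaled isometry of the truth.
    """
    tru, est = _aligned_coords(truth, estimate)
    a, b = tru.ravel(), est.ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance coordinate vector")
    return float(np.corrcoef(a, b)[0, 1])
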