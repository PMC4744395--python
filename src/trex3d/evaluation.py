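"""Assessment toolkit: accuracy metrics, TAD preservation, paired tests.

Structure estimates are scored by (i) RMSD and Pearson correlation of
the aligned coordinates (delegated to :mod:`trex3d.geometry`), (ii) how
well the known two-domain (TAD) organization survives estimation,
summarized as the ratio of the average silhouette width of the estimate
to that of the generating structure, and (iii) paired Wilcoxon
signed-rank comparisons between methods across simulation replicates.
A helper standardizes posterior median distances by a reference pair so
they can be compared with unit-free imaging (FISH) distances.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.metrics import silhouette_samples

from .model_core import Structure3D
from . import geometry
from .simulator import GoldStandard

__all__ = [
    "average_silhouette_width",
    "silhouette_ratio",
    "wilcoxon_signed_rank",
    "standardize_distances",
    "compare_methods",
    "evaluate_structure",
]


def average_silhouette_width(structure: Structure3D, labels) -> float:
    """Mean silhouette width of a domain labeling in 3D space.

    ``s(i) = (b(i) - a(i)) / max(a(i), b(i))`` with Euclidean distances;
    singleton clusters score 0.  Values near 1 mean tightly separated
    domains; near 0, no spatial domain structure.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != structure.n_loci:
        raise ValueError("labels length must match number of loci")
    if np.unique(labels).size < 2:
        raise ValueError("need at least two distinct labels")
    return float(np.mean(silhouette_samples(structure.coords, labels)))


def silhouette_ratio(estimate: Structure3D, truth: GoldStandard) -> float:
    """TAD-preservation score: ASW(estimate) / ASW(truth), true labels.

    1 for perfect recovery (or any isometry of the truth — silhouette
    only sees distances); values well below 1 mean the estimate blurred
    the domain separation.
    """
    labels = truth.domain_labels
    if estimate.n_loci != truth.n_loci:
        raise ValueError("estimate and truth must have the same loci")
    denom = average_silhouette_width(truth.structure, labels)
    if denom <= 0:
        raise ValueError("gold structure has non-positive silhouette width")
    return average_silhouette_width(estimate, labels) / denom


def wilcoxon_signed_rank(x, y, alternative: str = "two-sided") -> float:
    """Paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (Wilcoxon's convention); the exact
    null distribution is used for n <= 25 (ties handled by mid-rank
    permutation), otherwise the normal approximation with continuity
    correction.  Raises if every difference is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; test undefined")
    method = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=method,
                         correction=(method == "approx"),
                         zero_method="wilcox")
    return float(res.pvalue)


def standardize_distances(distance_summaries, reference_pair) -> dict:
    """Divide each pair's median distance by the reference pair's median.

    ``distance_summaries`` maps ``(i, j)`` to a median distance (or is a
    DataFrame with ``i``, ``j`` and ``median`` columns).  The reference
    pair maps to exactly 1; the operation is scale-invariant and
    idempotent.
    """
    if hasattr(distance_summaries, "iterrows"):
        summaries = {(int(r["i"]), int(r["j"])): float(r["median"])
                     for _, r in distance_summaries.iterrows()}
    else:
        summaries = {tuple(k): float(v) for k, v in distance_summaries.items()}
    ref = tuple(reference_pair)
    if ref not in summaries:
        raise ValueError(f"reference pair {ref} not among the summaries")
    ref_med = summaries[ref]
    if ref_med == 0:
        raise ValueError("reference pair has zero median distance")
    return {k: v / ref_med for k, v in summaries.items()}


def compare_methods(results, criterion: str = "rmsd",
                    baseline: str = "tREX",
                    alternative: str = "one-sided"):
    """Per-method Wilcoxon signed-rank p-values against a baseline.

    ``results`` is the tidy table from the simulation study (columns
    ``method``, ``pi``, ``replicate`` and the criterion).  For each
    non-baseline method and each resolution (``pi``) level, the paired
    test compares the baseline's replicate values with the method's.
    One-sided means "the baseline is better": smaller RMSD, larger
    correlation or silhouette ratio.  Returns a DataFrame with one row
    per (method, pi).
    """
    import pandas as pd

    if criterion not in ("rmsd", "sqrt_n_rmsd", "correlation",
                         "silhouette_ratio"):
        raise ValueError(f"unknown criterion {criterion!r}")
    smaller_is_better = criterion in ("rmsd", "sqrt_n_rmsd")
    if alternative == "one-sided":
        alt = "less" if smaller_is_better else "greater"
    else:
        alt = "two-sided"

    rows = []
    for (method, pi), grp in results[results["method"] != baseline].groupby(
            ["method", "pi"]):
        base = results[(results["method"] == baseline)
                       & (results["pi"] == pi)]
        merged = grp.merge(base, on=["setting", "replicate"],
                           suffixes=("_m", "_b"))
        if merged.empty:
            raise ValueError(f"no paired replicates for {method} vs "
                             f"{baseline} at pi={pi}")
        p = wilcoxon_signed_rank(merged[f"{criterion}_b"],
                                 merged[f"{criterion}_m"],
                                 alternative=alt)
        rows.append({"method": method, "pi": pi, "criterion": criterion,
                     "baseline": baseline, "p_value": p,
                     "n_pairs": len(merged)})
    return pd.DataFrame(rows)


def evaluate_structure(estimate: Structure3D, truth: GoldStandard) -> dict:
    """All structure-level scores for one estimate against the truth."""
    r = geometry.rmsd(truth.structure, estimate)
    return {
        "rmsd": r,
        "sqrt_n_rmsd": float(np.sqrt(truth.n_loci)) * r,
        "correlation": geometry.aligned_correlation(truth.structure, estimate),
        "silhouette_ratio": silhouette_ratio(estimate, truth),
    }
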