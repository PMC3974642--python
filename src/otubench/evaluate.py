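"""Clustering and detection performance evaluation.

Implements partitioning around medoids (PAM: greedy BUILD then
strictly-improving SWAP on a precomputed dissimilarity matrix), the
benchmark's clustering accuracy (discarded samples count as incorrectly
clustered, so accuracy can fall below the 50% all-in-one-cluster floor),
rank-based ROC AUC for differential-abundance result tables, the
false-positive sign diagnostic, and the rarefying-threshold sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import distances as dist_mod
from .normalize import (
    choose_rarefy_threshold,
    common_scale_moments,
    fit_dispersion_trend,
    rarefy,
    rle_size_factors,
    to_proportions,
    vst,
)
from .nb_tests import estimate_dispersion
from .simulate import CountMatrix, ExperimentDesign

__all__ = [
    "ClusteringResult",
    "pam",
    "clustering_accuracy",
    "max_achievable_accuracy",
    "roc_auc",
    "fp_sign_summary",
    "simulation_a_accuracy",
    "threshold_sweep",
]


@dataclass(frozen=True)
class ClusteringResult:
    """PAM output: cluster assignment of retained samples plus diagnostics."""

    cluster_of_sample: dict = field(repr=False)
    medoids: tuple
    objective: float
    objective_trace: tuple = ()
    discarded_samples: frozenset = frozenset()


def _as_matrix(dist) -> tuple[np.ndarray, list]:
    if isinstance(dist, pd.DataFrame):
        return dist.to_numpy(float), list(dist.index)
    arr = np.asarray(dist, dtype=float)
    return arr, [f"S{j + 1:03d}" for j in range(arr.shape[0])]


def pam(dist, k: int = 2, seed: int = 0, discarded=()) -> ClusteringResult:
    """Partitioning around medoids on a precomputed dissimilarity matrix.

    BUILD greedily picks the k medoids that most reduce total
    dissimilarity; SWAP repeatedly applies the best strictly-improving
    medoid/non-medoid exchange.  Ties prefer the lowest sample index, so
    the procedure is deterministic for a fixed matrix (``seed`` is
    accepted for interface uniformity but never consumed).
    """
    d, ids = _as_matrix(dist)
    n = d.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of samples")
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
        raise ValueError("dist must be symmetric, non-negative, zero-diagonal")

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        nearest = d[:, medoids].min(axis=1)
        gains = np.array(
            [
                np.maximum(nearest - d[:, c], 0.0).sum() if c not in medoids else -1.0
                for c in range(n)
            ]
        )
        medoids.append(int(np.argmax(gains)))

    def objective(meds: list[int]) -> float:
        return float(d[:, meds].min(axis=1).sum())

    obj = objective(medoids)
    trace = [obj]
    # SWAP
    improved = True
    while improved:
        improved = False
        best = (0.0, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                cand = medoids.copy()
                cand[mi] = h
                delta = objective(cand) - obj
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, h))
        if best[1] is not None:
            mi, h = best[1]
            medoids[mi] = h
            obj = objective(medoids)
            trace.append(obj)
            improved = True

    medoids = sorted(medoids)
    assign = np.argmin(d[:, medoids], axis=1)
    return ClusteringResult(
        cluster_of_sample={ids[j]: int(assign[j]) for j in range(n)},
        medoids=tuple(ids[m] for m in medoids),
        objective=obj,
        objective_trace=tuple(trace),
        discarded_samples=frozenset(discarded),
    )


def clustering_accuracy(result: ClusteringResult, truth_labels: dict, n_total: int) -> float:
    """Fraction of all samples correctly clustered, discards counting wrong.

    The two cluster labels are mapped to the two true classes in the way
    that maximizes the number of correct retained samples; discarded
    samples can never be correct; the denominator is the full sample
    count.  With everything retained and balanced classes the floor is
    0.5 (one big cluster); discarding pushes below it.
    """
    retained = list(result.cluster_of_sample)
    if n_total < len(retained):
        raise ValueError("n_total smaller than the retained sample count")
    classes = sorted({truth_labels[s] for s in truth_labels})
    if len(classes) != 2:
        raise ValueError("accuracy defined for two-class truth")
    correct = 0
    for mapping in ((0, 1), (1, 0)):
        hits = sum(
            1
            for s in retained
            if classes[mapping[result.cluster_of_sample[s] % 2]] == truth_labels[s]
        )
        correct = max(correct, hits)
    return correct / n_total


def max_achievable_accuracy(n_discarded: int, n_total: int) -> float:
    """Upper bound on accuracy once samples have been discarded."""
    if not (0 <= n_discarded <= n_total):
        raise ValueError("need 0 <= n_discarded <= n_total")
    return (n_total - n_discarded) / n_total


def roc_auc(scores, truth_flags) -> float:
    """Rank-based (Mann-Whitney) AUC; ties get half credit."""
    truth = np.asarray(truth_flags, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("AUC undefined without both positives and negatives")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


def auc_from_results(results: pd.DataFrame) -> float:
    """AUC of a test-result table: positives ranked by -p (raw, not adjusted)."""
    return roc_auc(-results["p"].to_numpy(), results["is_true_positive"].to_numpy())


def fp_sign_summary(results: pd.DataFrame, alpha: float = 0.05) -> float:
    """Direction consistency of false positives at the BH threshold.

    Among detected OTUs (adjusted p <= alpha) that are not true
    positives, returns the fraction whose direction says the OTU is more
    abundant in the null class — oriented so the benchmark's systematic
    artifact (unperturbed OTUs dragged down in the test class by inflated
    libraries) reads as 1.0.  NaN when there are no false positives.
    """
    detected = results[results["p_adj"] <= alpha]
    fps = detected[~detected["is_true_positive"]]
    if len(fps) == 0:
        return float("nan")
    return float((fps["direction"] < 0).mean())


_SIMPLE_METRICS = {
    "bray": dist_mod.bray_curtis,
    "euclidean": dist_mod.euclidean,
}


def _distance_matrix(
    counts: CountMatrix, normalization: str, distance: str, tree=None, seed: int = 0,
    rarefy_quantile: float = 0.15,
) -> tuple[pd.DataFrame, list]:
    """Distance matrix for one normalization x distance combination.

    Returns (matrix over retained samples, list of discarded sample ids).
    """
    discarded: list = []
    if normalization == "rarefy":
        depth = choose_rarefy_threshold(counts.library_sizes, rarefy_quantile)
        rare = rarefy(counts, depth, seed=seed)
        discarded = [s for s in counts.sample_ids if s not in rare.sample_ids]
        counts = rare

    if distance == "poisson":
        mat = dist_mod.pairwise_distances(
            counts.counts, dist_mod.poisson_dissimilarity,
            sample_ids=counts.sample_ids,
        )
        return mat, discarded
    if distance == "top_msd":
        mat = dist_mod.pairwise_distances(
            counts.counts, dist_mod.top_msd, sample_ids=counts.sample_ids
        )
        return mat, discarded
    if distance == "unifrac_u":
        mat = dist_mod.pairwise_distances(
            counts.counts,
            dist_mod.unifrac_unweighted,
            sample_ids=counts.sample_ids,
            tree=tree,
            otu_ids=counts.otu_ids,
        )
        return mat, discarded
    if distance == "unifrac_w":
        mat = dist_mod.pairwise_distances(
            to_proportions(counts),
            dist_mod.unifrac_weighted,
            sample_ids=counts.sample_ids,
            tree=tree,
            otu_ids=counts.otu_ids,
        )
        return mat, discarded

    if normalization in ("none", "rarefy"):
        values = counts.counts.astype(float)
    elif normalization == "proportion":
        values = to_proportions(counts)
    elif normalization == "vst":
        # unsupervised ("blind") trend fit: class labels are unknown to a
        # clustering workflow, so between-class differences inflate alpha
        sf = rle_size_factors(counts)
        fit = fit_dispersion_trend(common_scale_moments(counts, sf))
        values = vst(counts, sf, fit.alpha)
    else:
        raise ValueError(f"unknown normalization: {normalization}")
    metric = _SIMPLE_METRICS[distance]
    mat = dist_mod.pairwise_distances(values, metric, sample_ids=counts.sample_ids)
    return mat, discarded


def simulation_a_accuracy(
    counts: CountMatrix,
    design: ExperimentDesign,
    normalization: str,
    distance: str,
    tree=None,
    seed: int = 0,
    rarefy_quantile: float = 0.15,
) -> dict:
    """Cluster one simulated two-class experiment and score the accuracy."""
    mat, discarded = _distance_matrix(
        counts, normalization, distance, tree=tree, seed=seed,
        rarefy_quantile=rarefy_quantile,
    )
    result = pam(mat, k=2, discarded=discarded)
    truth = dict(zip(counts.sample_ids, design.class_of_sample))
    acc = clustering_accuracy(result, truth, n_total=len(counts.sample_ids))
    return {
        "normalization": normalization,
        "distance": distance,
        "accuracy": acc,
        "n_discarded": len(discarded),
        "max_achievable_accuracy": max_achievable_accuracy(
            len(discarded), len(counts.sample_ids)
        ),
    }


def threshold_sweep(
    counts: CountMatrix,
    design: ExperimentDesign,
    quantile_grid,
    distances=("bray", "euclidean"),
    seed: int = 0,
) -> pd.DataFrame:
    """Clustering accuracy after rarefying at a grid of threshold quantiles.

    Rarefying is the only normalization; each grid point rarefies at that
    library-size quantile, computes each distance on the rarefied counts,
    clusters with PAM (k=2) and scores accuracy against the design.  A
    threshold that discards every sample is recorded with accuracy 0 and
    ``all_discarded`` set.
    """
    rows = []
    n_total = len(counts.sample_ids)
    truth = dict(zip(counts.sample_ids, design.class_of_sample))
    for qi, q in enumerate(quantile_grid):
        depth = choose_rarefy_threshold(counts.library_sizes, q)
        try:
            rare = rarefy(counts, depth, seed=seed + qi)
        except ValueError:
            for dist_name in distances:
                rows.append(
                    {
                        "quantile": q,
                        "depth": depth,
                        "distance": dist_name,
                        "accuracy": 0.0,
                        "n_discarded": n_total,
                        "max_achievable_accuracy": 0.0,
                        "all_discarded": True,
                    }
                )
            continue
        discarded = [s for s in counts.sample_ids if s not in rare.sample_ids]
        for dist_name in distances:
            mat = dist_mod.pairwise_distances(
                rare.counts.astype(float),
                _SIMPLE_METRICS[dist_name],
                sample_ids=rare.sample_ids,
            )
            result = pam(mat, k=2, discarded=discarded)
            acc = clustering_accuracy(result, truth, n_total=n_total)
            rows.append(
                {
                    "quantile": q,
                    "depth": depth,
                    "distance": dist_name,
                    "accuracy": acc,
                    "n_discarded": len(discarded),
                    "max_achievable_accuracy": max_achievable_accuracy(
                        len(discarded), n_total
                    ),
                    "all_discarded": False,
                }
            )
    return pd.DataFrame(rows)
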