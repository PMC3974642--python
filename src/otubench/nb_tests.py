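"""Differential-abundance tests for two-class OTU count experiments.

Three tests are compared by the benchmark:

* an exact Negative Binomial test conditioned on the total of the two
  group sums (the edgeR/DESeq-style exact test, one implementation
  parameterized by the size factors supplied);
* a Negative Binomial Wald test from a per-OTU log-link GLM with a class
  indicator and log size-factor offset;
* the two-sided Welch t-test applied to whatever per-sample values the
  normalization condition dictates (raw counts, rarefied counts, or
  proportions).

All raw p values are corrected with Benjamini-Hochberg; detection means
adjusted p <= 0.05.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.api import GLM, families
from statsmodels.stats.multitest import multipletests

from .normalize import (
    DispersionFit,
    SizeFactors,
    choose_rarefy_threshold,
    fit_dispersion_trend,
    pooled_common_scale_moments,
    rarefy,
    rle_size_factors,
    to_proportions,
)
from .simulate import NULL_CLASS, TEST_CLASS, CountMatrix, ExperimentDesign

__all__ = [
    "nb_pmf",
    "nb_exact_test",
    "nb_wald_test",
    "welch_t",
    "bh_adjust",
    "run_da_experiment",
]

_TIE_REL = 1e-7  # relative tolerance for including probability ties


def _nb_logpmf(k, mean: float, variance: float) -> np.ndarray:
    """log pmf of the NB parameterized by mean and variance (Poisson if v<=m)."""
    k = np.asarray(k)
    if variance <= mean * (1 + 1e-12):
        return stats.poisson.logpmf(k, mean)
    r = mean**2 / (variance - mean)
    p = r / (r + mean)
    return stats.nbinom.logpmf(k, r, p)


def nb_pmf(k, mean: float, phi: float) -> np.ndarray:
    """NB pmf with mean m and variance m + phi*m^2; Poisson at phi = 0."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    return np.exp(_nb_logpmf(k, mean, mean + phi * mean**2))


def nb_exact_test(
    counts_a,
    counts_b,
    size_factors_a,
    size_factors_b,
    phi: float,
) -> tuple[float, int]:
    """Exact NB test for one OTU, conditioning on the total of group sums.

    The group sums K_A and K_B are modeled as NB variables whose means
    and variances aggregate the per-sample NB model (mean s_j*mu,
    variance s_j*mu + phi*(s_j*mu)^2) with mu estimated from the pooled
    common-scale mean.  Conditional on T = K_A + K_B, the p value sums
    the probabilities of all splits (a, T-a) no more probable than the
    observed one, over the total probability of all splits.  Ties in the
    probability ordering are included in the rejection sum
    (conservative).  Returns (p, direction) with direction the sign of
    the common-scale group mean difference A minus B.
    """
    counts_a = np.asarray(counts_a, dtype=np.int64)
    counts_b = np.asarray(counts_b, dtype=np.int64)
    sf_a = np.asarray(size_factors_a, dtype=float)
    sf_b = np.asarray(size_factors_b, dtype=float)
    t_a, t_b = int(counts_a.sum()), int(counts_b.sum())
    total = t_a + t_b
    s_a, s_b = sf_a.sum(), sf_b.sum()
    direction = int(np.sign(t_a / s_a - t_b / s_b))
    if total == 0:
        return 1.0, 0
    mu = total / (s_a + s_b)
    mean_a, mean_b = mu * s_a, mu * s_b
    var_a = mean_a + phi * mu**2 * np.sum(sf_a**2)
    var_b = mean_b + phi * mu**2 * np.sum(sf_b**2)
    a = np.arange(total + 1)
    logp = _nb_logpmf(a, mean_a, var_a) + _nb_logpmf(total - a, mean_b, var_b)
    logp -= logp.max()
    w = np.exp(logp)
    p = float(w[w <= w[t_a] * (1 + _TIE_REL)].sum() / w.sum())
    return min(p, 1.0), direction


def nb_wald_test(
    counts_row,
    labels,
    size_factors,
    phi: float,
    ridge: float = 0.0,
) -> tuple[float, float]:
    """Wald test from a per-OTU NB log-link GLM with size-factor offset.

    The model is K_j ~ NB(exp(b0 + b1*x_j + log s_j), phi) with x_j the
    test-class indicator; the statistic is b1_hat / SE(b1_hat) with a
    two-sided normal p value.  ``ridge`` > 0 adds an L2 penalty on the
    coefficients (a crude stand-in for coefficient shrinkage priors);
    off by default.  Non-convergence or a degenerate fit is flagged with
    a warning and returns (0.0, 1.0), never silently.
    """
    y = np.asarray(counts_row, dtype=float)
    labels = np.asarray(labels)
    sf = np.asarray(size_factors, dtype=float)
    x = np.column_stack([np.ones_like(y), (labels == TEST_CLASS).astype(float)])
    family = families.Poisson() if phi == 0 else families.NegativeBinomial(alpha=phi)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if ridge > 0:
                res = GLM(y, x, family=family, offset=np.log(sf)).fit_regularized(
                    alpha=ridge, L1_wt=0.0
                )
            else:
                res = GLM(y, x, family=family, offset=np.log(sf)).fit()
        stat = float(res.params[1] / res.bse[1])
        if not np.isfinite(stat):
            raise ValueError("non-finite Wald statistic")
    except Exception:
        warnings.warn(
            "NB Wald GLM did not produce a finite statistic; reporting p = 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0, 1.0
    return stat, float(2 * stats.norm.sf(abs(stat)))


def welch_t(x, y) -> tuple[float, float]:
    """Two-sided Welch t-test (unequal variances, Satterthwaite df).

    Degenerate input (zero variance in both groups with equal means)
    returns (0.0, 1.0) by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = stats.ttest_ind(x, y, equal_var=False)
    if not np.isfinite(stat):
        return 0.0, 1.0
    return float(stat), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _result_table(otu_ids, statistic, p, direction, truth) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "otu_id": list(otu_ids),
            "statistic": np.asarray(statistic, dtype=float),
            "p": np.asarray(p, dtype=float),
            "p_adj": bh_adjust(p),
            "direction": np.asarray(direction, dtype=int),
            "is_true_positive": np.asarray(truth, dtype=bool),
        }
    )


def estimate_dispersion(
    counts: CountMatrix, labels, size_factors: SizeFactors
) -> DispersionFit:
    """Pooled-moment dispersion trend for a two-class experiment."""
    moments = pooled_common_scale_moments(counts, size_factors, labels)
    return fit_dispersion_trend(moments)


def run_da_experiment(
    counts: CountMatrix,
    design: ExperimentDesign,
    test: str,
    normalization: str,
    seed: int = 0,
    rarefy_quantile: float = 0.15,
) -> pd.DataFrame:
    """Run one test x normalization combination on a simulated experiment.

    ``test`` is one of ``welch``, ``nb_exact``, ``nb_wald``;
    ``normalization`` one of ``none`` (raw counts / parametric model),
    ``rarefied`` (subsample to the 15th-percentile threshold first), or
    ``proportion`` (Welch only).  Returns a per-OTU result table with BH
    adjusted p values, direction (sign of test-minus-null difference) and
    the ground-truth flag; OTUs with zero counts in every retained sample
    are filtered before testing (count in ``df.attrs['n_filtered']``).
    """
    if design.sim_kind != "B":
        raise ValueError("differential abundance applies to Simulation B designs")
    labels = design.labels
    if normalization == "rarefied":
        depth = choose_rarefy_threshold(counts.library_sizes, rarefy_quantile)
        rare = rarefy(counts, depth, seed=seed)
        keep = [counts.sample_ids.index(s) for s in rare.sample_ids]
        counts, labels = rare, labels[keep]
    elif normalization not in ("none", "proportion"):
        raise ValueError(f"unknown normalization: {normalization}")

    nonzero = counts.counts.sum(axis=1) > 0
    n_filtered = int((~nonzero).sum())
    cm = CountMatrix(
        counts.counts[nonzero],
        tuple(np.asarray(counts.otu_ids, dtype=object)[nonzero]),
        counts.sample_ids,
    )
    mask_t = labels == TEST_CLASS
    mask_n = labels == NULL_CLASS
    truth = [o in design.perturbed_otus for o in cm.otu_ids]

    if test == "welch":
        if normalization == "proportion":
            values = to_proportions(cm)
        else:
            values = cm.counts.astype(float)
        stats_, ps = zip(
            *(welch_t(row[mask_t], row[mask_n]) for row in values)
        )
        dirs = [int(np.sign(s)) for s in stats_]
        df = _result_table(cm.otu_ids, stats_, ps, dirs, truth)
    elif test in ("nb_exact", "nb_wald"):
        if normalization == "proportion":
            raise ValueError("NB tests operate on counts, not proportions")
        sf = rle_size_factors(cm)
        phi = estimate_dispersion(cm, labels, sf).alpha
        if test == "nb_exact":
            sf_t, sf_n = sf.factors[mask_t], sf.factors[mask_n]
            ps, dirs = zip(
                *(
                    nb_exact_test(row[mask_t], row[mask_n], sf_t, sf_n, phi)
                    for row in cm.counts
                )
            )
            stats_ = [
                -stats.norm.ppf(max(min(p, 1 - 1e-16), 1e-300) / 2) * d
                for p, d in zip(ps, dirs)
            ]
        else:
            stats_, ps = zip(
                *(
                    nb_wald_test(row, labels, sf.factors, phi)
                    for row in cm.counts
                )
            )
            dirs = [int(np.sign(s)) for s in stats_]
        df = _result_table(cm.otu_ids, stats_, ps, dirs, truth)
    else:
        raise ValueError(f"unknown test: {test}")

    df.attrs["n_filtered"] = n_filtered
    df.attrs["test"] = test
    df.attrs["normalization"] = normalization
    return df
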