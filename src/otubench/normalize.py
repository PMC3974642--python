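"""Library-size normalizations and overdispersion machinery.

Covers the full menu compared in the benchmark: rarefying (subsample
without replacement to a common depth, discarding small libraries),
simple proportions, deterministic common-scale rounding, median-of-ratios
(RLE) size factors, upper-quartile factors, common-scale moment
estimates, the quadratic mean-variance trend fit, and the closed-form
variance-stabilizing transformation it implies.

The count model throughout is Negative Binomial: K_ij ~ NB with mean
s_j * mu_i and variance m + phi * m^2, Poisson at phi = 0.  The trend fit
estimates the single quadratic coefficient alpha of v = mu + alpha*mu^2
across OTUs; the VST for that trend is u(x) = (2/sqrt(alpha)) *
asinh(sqrt(alpha*x)), degenerating to 2*sqrt(x) at alpha = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .simulate import CountMatrix

__all__ = [
    "SizeFactors",
    "CommonScaleMoments",
    "DispersionFit",
    "choose_rarefy_threshold",
    "rarefy",
    "to_proportions",
    "common_scale_round",
    "rle_size_factors",
    "uq_factor",
    "common_scale_moments",
    "fit_dispersion_trend",
    "vst",
]


@dataclass(frozen=True)
class SizeFactors:
    """One positive scaling constant per sample, geometric mean 1."""

    factors: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.factors, dtype=float)
        if np.any(f <= 0):
            raise ValueError("size factors must be positive")
        object.__setattr__(self, "factors", f)


@dataclass(frozen=True)
class CommonScaleMoments:
    """Per-OTU mean and variance of counts placed on a common scale."""

    mean: np.ndarray = field(repr=False)
    variance: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.mean, dtype=float)
        v = np.asarray(self.variance, dtype=float)
        if m.shape != v.shape:
            raise ValueError("mean/variance shape mismatch")
        if np.any(m < 0) or np.any(v < 0):
            raise ValueError("moments must be non-negative")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "variance", v)


@dataclass(frozen=True)
class DispersionFit:
    """Quadratic mean-variance trend v = mu + alpha*mu^2 plus per-OTU phi."""

    alpha: float
    phi: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        phi = np.asarray(self.phi, dtype=float)
        if np.any(phi < 0):
            raise ValueError("phi must be >= 0")
        object.__setattr__(self, "phi", phi)

    def trend(self, mu) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        return mu + self.alpha * mu**2


def _counts_array(counts) -> np.ndarray:
    if isinstance(counts, CountMatrix):
        return counts.counts
    return np.asarray(counts)


def choose_rarefy_threshold(library_sizes, quantile: float = 0.15) -> int:
    """Empirical quantile of library sizes under the nearest-rank rule.

    Default 0.15: the minimum-library threshold is set to the 15th
    percentile of library sizes within each simulated experiment.
    quantile 0 returns the minimum.
    """
    sizes = np.sort(np.asarray(library_sizes, dtype=np.int64))
    if sizes.size == 0:
        raise ValueError("library_sizes is empty")
    if not (0.0 <= quantile < 1.0):
        raise ValueError("quantile must be in [0, 1)")
    rank = max(1, int(np.ceil(quantile * sizes.size)))
    return int(sizes[rank - 1])


def rarefy(counts: CountMatrix, depth: int, seed: int = 0) -> CountMatrix:
    """Rarefy: discard small samples, subsample the rest to a common depth.

    Samples with library size below ``depth`` are dropped; each remaining
    column is replaced by a multivariate-hypergeometric subsample (drawing
    ``depth`` reads without replacement from the column's read multiset),
    so every retained column sums exactly to ``depth``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    libs = counts.library_sizes
    keep = np.flatnonzero(libs >= depth)
    if keep.size == 0:
        raise ValueError("rarefying discarded every sample")
    rng = np.random.default_rng(seed)
    sub = np.column_stack(
        [rng.multivariate_hypergeometric(counts.counts[:, j], depth) for j in keep]
    )
    return CountMatrix(
        sub, counts.otu_ids, tuple(np.asarray(counts.sample_ids, dtype=object)[keep])
    )


def to_proportions(counts) -> np.ndarray:
    """Divide each column by its library size; columns sum to 1."""
    arr = _counts_array(counts).astype(float)
    sums = arr.sum(axis=0)
    if np.any(sums == 0):
        raise ValueError("zero-sum column: proportions undefined")
    return arr / sums


def common_scale_round(counts, target_size: int) -> CountMatrix:
    """Deterministic alternative to rarefying: round expected counts.

    Each entry becomes round(target_size * k_ij / s_j) with half-to-even
    rounding (numpy's default), so all columns are on a common scale
    without the artificial sampling noise of the random subsampling step.
    No seed is consumed.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    cm = counts if isinstance(counts, CountMatrix) else CountMatrix(
        np.asarray(counts),
        tuple(f"OTU{i}" for i in range(np.asarray(counts).shape[0])),
        tuple(f"S{j}" for j in range(np.asarray(counts).shape[1])),
    )
    sums = cm.library_sizes.astype(float)
    if np.any(sums == 0):
        raise ValueError("zero-sum column")
    scaled = np.rint(target_size * cm.counts / sums).astype(np.int64)
    return CountMatrix(scaled, cm.otu_ids, cm.sample_ids)


def _geometric_mean_one(factors: np.ndarray) -> np.ndarray:
    return factors / np.exp(np.mean(np.log(factors)))


def rle_size_factors(counts) -> SizeFactors:
    """Median-of-ratios ("relative log expression") size factors.

    s_j = median over reference OTUs of k_ij / geomean_i(k_i.), using as
    reference the OTUs observed in every sample (the classic estimator's
    requirement).  Factors are rescaled to geometric mean 1.  Sparse
    microbiome tables can have no all-positive OTU; the estimator then
    falls back to library-size proportionality with a warning.
    """
    arr = _counts_array(counts).astype(float)
    positive = np.all(arr > 0, axis=1)
    if not positive.any():
        warnings.warn(
            "no OTU observed in all samples; falling back to library-size "
            "proportional size factors",
            RuntimeWarning,
            stacklevel=2,
        )
        factors = arr.sum(axis=0)
    else:
        ref = arr[positive]
        geomean = np.exp(np.mean(np.log(ref), axis=1, keepdims=True))
        factors = np.median(ref / geomean, axis=0)
    return SizeFactors(_geometric_mean_one(factors))


def uq_factor(counts) -> SizeFactors:
    """Upper-quartile size factors: Q75 of nonzero counts over library size.

    Linear-interpolation percentile of each sample's nonzero counts,
    divided by the sample's library size, rescaled to geometric mean 1.
    """
    arr = _counts_array(counts).astype(float)
    sums = arr.sum(axis=0)
    factors = np.empty(arr.shape[1])
    for j in range(arr.shape[1]):
        nz = arr[arr[:, j] > 0, j]
        if nz.size == 0:
            raise ValueError(f"column {j} is all zero")
        factors[j] = np.percentile(nz, 75) / sums[j]
    return SizeFactors(_geometric_mean_one(factors))


def common_scale_moments(counts, size_factors: SizeFactors) -> CommonScaleMoments:
    """Per-OTU mean and unbiased variance of k_ij / s_j across replicates."""
    arr = _counts_array(counts).astype(float)
    if arr.shape[1] < 2:
        raise ValueError("variance undefined with a single sample")
    z = arr / size_factors.factors
    return CommonScaleMoments(z.mean(axis=1), z.var(axis=1, ddof=1))


def pooled_common_scale_moments(
    counts, size_factors: SizeFactors, labels
) -> CommonScaleMoments:
    """Common-scale moments pooling within-class variation across two classes.

    The mean is taken over all samples; the variance pools within-class
    sums of squares (denominator n - n_classes), so a real class effect
    does not masquerade as biological dispersion.
    """
    arr = _counts_array(counts).astype(float)
    labels = np.asarray(labels)
    z = arr / size_factors.factors
    levels = np.unique(labels)
    ss = np.zeros(arr.shape[0])
    n_eff = 0
    for lv in levels:
        zc = z[:, labels == lv]
        if zc.shape[1] < 2:
            continue
        ss += ((zc - zc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        n_eff += zc.shape[1] - 1
    if n_eff == 0:
        raise ValueError("no class has >= 2 samples; variance undefined")
    return CommonScaleMoments(z.mean(axis=1), ss / n_eff)


def fit_dispersion_trend(moments: CommonScaleMoments) -> DispersionFit:
    """Fit v = mu + alpha*mu^2 across OTUs, alpha constrained >= 0.

    Per-OTU excess dispersion z_i = (v_i - mu_i)/mu_i^2 is averaged with
    weights mu_i^2 (down-weighting low-mean OTUs whose moment estimates
    are noisy), which is the least-squares solution of (v - mu) = alpha *
    mu^2 under those weights; exact data v = mu + a*mu^2 recovers a
    exactly.  Per-OTU phi_i = max(0, z_i); the "fit-only" sharing mode
    used by the tests assigns every OTU the trend value alpha.
    """
    mu, v = moments.mean, moments.variance
    ok = mu > 0
    if ok.sum() < 5:
        raise ValueError("need >= 5 OTUs with positive mean")
    mu_ok, v_ok = mu[ok], v[ok]
    alpha = max(0.0, float(np.sum(v_ok - mu_ok) / np.sum(mu_ok**2)))
    phi = np.zeros_like(mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (v - mu) / mu**2
    phi[ok] = np.maximum(0.0, raw[ok])
    return DispersionFit(alpha=alpha, phi=phi)


def vst(counts, size_factors: SizeFactors, alpha: float) -> np.ndarray:
    """Closed-form variance-stabilizing transformation for the NB trend.

    Common-scale values x = k/s are mapped through
    u(x) = (2/sqrt(alpha)) * asinh(sqrt(alpha * x)) for alpha > 0 and
    u(x) = 2*sqrt(x) at alpha = 0 (the Poisson square-root limit); u is
    continuous in alpha and strictly increasing in x.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    arr = _counts_array(counts).astype(float)
    x = arr / np.asarray(size_factors.factors, dtype=float)
    if alpha == 0:
        return 2.0 * np.sqrt(x)
    return (2.0 / np.sqrt(alpha)) * np.arcsinh(np.sqrt(alpha * x))
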