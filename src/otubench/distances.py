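"""Sample-wise distance and dissimilarity measures.

The clustering benchmark pairs each normalization with a distance:
Bray-Curtis, Euclidean, a size-factor-normalized Poisson deviance
("PoissonDist"), the mean squared difference of top log-fold-changes
after upper-quartile normalization ("top-MSD"), and unweighted/weighted
UniFrac over a rooted phylogeny (delegated to scikit-bio).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis, euclidean as _euclidean
from skbio import TreeNode
from skbio.diversity.beta import unweighted_unifrac as _skbio_uu

__all__ = [
    "bray_curtis",
    "euclidean",
    "poisson_dissimilarity",
    "top_msd",
    "unifrac_unweighted",
    "unifrac_weighted",
    "pairwise_distances",
]


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("inputs must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two empty samples")
    return float(braycurtis(x, y))


def euclidean(x, y) -> float:
    """Euclidean distance treating each OTU as a dimension."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    return float(_euclidean(x, y))


def poisson_dissimilarity(x, y, size_factors=None) -> float:
    """Poisson deviance between two count profiles on a common scale.

    Models x_i ~ Poisson(s1*mu_i), y_i ~ Poisson(s2*mu_i) and sums, over
    OTUs, twice the log-likelihood-ratio of separate versus common means:
    d = 2 * sum_i [ x_i log(x_i/(s1*m_i)) + y_i log(y_i/(s2*m_i)) ] with
    m_i = (x_i+y_i)/(s1+s2) and 0*log0 = 0.  Size factors default to the
    pair's library sizes, so a pure depth difference scores 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("inputs must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        return 0.0
    if size_factors is None:
        s1, s2 = x.sum(), y.sum()
    else:
        s1, s2 = float(size_factors[0]), float(size_factors[1])
    mu = (x + y) / (s1 + s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        term_x = np.where(x > 0, x * np.log(x / (s1 * mu)), 0.0)
        term_y = np.where(y > 0, y * np.log(y / (s2 * mu)), 0.0)
    return float(2.0 * (np.nansum(term_x) + np.nansum(term_y)))


def top_msd(x, y, n_top: int = 500, pseudocount: float = 0.5) -> float:
    """RMS of the largest log-fold-changes after upper-quartile scaling.

    Each sample is divided by the 75th percentile of its nonzero counts
    (exactly scale invariant), a pseudo-count is added, and the root mean
    square of the ``n_top`` largest absolute log2 fold changes is
    returned.  With fewer OTUs than ``n_top`` all are used, with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")

    def _scale(v: np.ndarray) -> np.ndarray:
        nz = v[v > 0]
        if nz.size == 0:
            raise ValueError("all-zero sample")
        return v / np.percentile(nz, 75)

    lfc = np.log2(_scale(x) + pseudocount) - np.log2(_scale(y) + pseudocount)
    if lfc.size < n_top:
        warnings.warn(
            f"only {lfc.size} OTUs available for top-MSD (n_top={n_top}); using all",
            RuntimeWarning,
            stacklevel=2,
        )
        n_top = lfc.size
    top = np.sort(np.abs(lfc))[-n_top:]
    return float(np.sqrt(np.mean(top**2)))


def unifrac_unweighted(presence_x, presence_y, tree: TreeNode, otu_ids) -> float:
    """Unweighted UniFrac: unique branch length over covered branch length.

    Presence means count >= 1; the root edge is excluded (scikit-bio's
    convention).
    """
    x = (np.asarray(presence_x) >= 1).astype(int)
    y = (np.asarray(presence_y) >= 1).astype(int)
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("UniFrac undefined for two empty samples")
    return float(_skbio_uu(x, y, taxa=list(otu_ids), tree=tree))


def unifrac_weighted(
    props_x, props_y, tree: TreeNode, otu_ids, normalized: bool = True
) -> float:
    """Weighted UniFrac: branch-length-weighted subtree mass differences.

    Sums b_len * |A_b - B_b| over branches, where A_b and B_b are the
    proportion mass of each sample in the subtree below the branch.
    Inputs are proportion vectors over the tree's leaves; non-normalized
    input is renormalized with a warning.  The normalized variant (the
    default) divides by the maximum attainable value for the pair,
    sum_j (x_j + y_j) * depth_j with depth_j the leaf's root distance.
    """
    x = np.asarray(props_x, dtype=float)
    y = np.asarray(props_y, dtype=float)
    for v in (x, y):
        if v.sum() <= 0:
            raise ValueError("UniFrac undefined for an empty sample")
    if abs(x.sum() - 1) > 1e-9 or abs(y.sum() - 1) > 1e-9:
        warnings.warn(
            "weighted UniFrac input not normalized; renormalizing",
            RuntimeWarning,
            stacklevel=2,
        )
        x = x / x.sum()
        y = y / y.sum()
    mass = {name: (xi, yi) for name, xi, yi in zip(otu_ids, x, y)}

    raw = 0.0
    denom = 0.0
    subtree: dict[int, tuple[float, float]] = {}
    for node in tree.postorder():
        if node.is_tip():
            mx, my = mass[node.name]
        else:
            mx = sum(subtree[id(c)][0] for c in node.children)
            my = sum(subtree[id(c)][1] for c in node.children)
        subtree[id(node)] = (mx, my)
        if node.parent is not None and node.length:
            raw += node.length * abs(mx - my)
    if not normalized:
        return raw
    for tip in tree.tips():
        depth = 0.0
        node = tip
        while node.parent is not None:
            depth += node.length or 0.0
            node = node.parent
        mx, my = mass[tip.name]
        denom += (mx + my) * depth
    return raw / denom if denom > 0 else 0.0


def pairwise_distances(values, metric, sample_ids=None, **kwargs) -> pd.DataFrame:
    """Assemble a symmetric zero-diagonal distance matrix from a pair metric.

    ``values`` has samples as columns; ``metric`` is any of this module's
    two-sample functions (extra keyword arguments are forwarded).
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    if sample_ids is None:
        sample_ids = [f"S{j + 1:03d}" for j in range(n)]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = metric(values[:, i], values[:, j], **kwargs)
            if d < 0:
                raise ValueError("distance metric returned a negative value")
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=list(sample_ids), columns=list(sample_ids))
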