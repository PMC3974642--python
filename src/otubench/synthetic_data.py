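"""Synthetic community templates, library sizes, and random phylogenies.

Real microbiome surveys provide two ingredients the simulation frameworks
need: per-environment multinomial OTU proportion profiles with a
heavy-tailed rank-abundance shape, and a heavy-tailed distribution of
per-sample sequencing depths (library sizes).  This module generates both
from scratch, plus a random rooted tree over the OTUs so that
phylogenetic distances (UniFrac) can be computed downstream.

Every stochastic operation consumes an explicit integer seed; identical
seeds reproduce identical output bit for bit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "TemplateProfile",
    "LibrarySizeDraw",
    "make_template",
    "make_disjoint_pair",
    "sample_library_sizes",
    "make_random_tree",
]


@dataclass(frozen=True)
class TemplateProfile:
    """A multinomial proportion vector over OTUs for one environment.

    Plays the role of the per-feature mean proportions mu_i of a
    community: a single draw of a sample with library size s is
    Multinomial(s, proportions).
    """

    otu_ids: tuple[str, ...]
    proportions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        props = np.asarray(self.proportions, dtype=float)
        object.__setattr__(self, "proportions", props)
        object.__setattr__(self, "otu_ids", tuple(self.otu_ids))
        if len(self.otu_ids) != props.size:
            raise ValueError("otu_ids and proportions length mismatch")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("otu_ids must be unique")
        if np.any(props < 0):
            raise ValueError("proportions must be non-negative")
        if abs(props.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must sum to 1 within 1e-12")

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def to_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=list(self.otu_ids), name="proportion")

    def write_tsv(self, path) -> None:
        df = self.to_series().rename_axis("otu_id").reset_index()
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TemplateProfile":
        df = pd.read_csv(path, sep="\t", dtype={"otu_id": str})
        return cls(tuple(df["otu_id"]), df["proportion"].to_numpy(float))


@dataclass(frozen=True)
class LibrarySizeDraw:
    """Realized per-sample sequencing depths plus the draw's provenance."""

    sizes: np.ndarray = field(repr=False)
    target_median: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=np.int64)
        object.__setattr__(self, "sizes", sizes)
        if np.any(sizes < 1):
            raise ValueError("library sizes must be >= 1")

    @property
    def n(self) -> int:
        return self.sizes.size


def make_template(n_otus: int, decay: float = 0.99, seed: int = 0) -> TemplateProfile:
    """Geometric-series rank-abundance template with shuffled rank order.

    Proportions are p_r proportional to decay**r for ranks r = 0..n-1,
    normalized, then assigned to OTU ids in a seed-determined shuffled
    order so abundance is not correlated with the id ordering.  decay=1
    gives a uniform community; small decay gives strong dominance.
    """
    if n_otus < 1:
        raise ValueError("n_otus must be >= 1")
    if not (0.0 < decay <= 1.0):
        raise ValueError("decay must be in (0, 1]")
    ranks = np.arange(n_otus, dtype=float)
    props = np.power(decay, ranks)
    props /= props.sum()
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_otus)
    otu_ids = tuple(f"OTU{i + 1:04d}" for i in range(n_otus))
    shuffled = np.empty_like(props)
    shuffled[order] = props
    # renormalize defensively against accumulated rounding
    shuffled = shuffled / shuffled.sum()
    return TemplateProfile(otu_ids, shuffled)


def make_disjoint_pair(
    n_otus_each: int, decay: float = 0.99, seed: int = 0
) -> tuple[TemplateProfile, TemplateProfile]:
    """Two templates over a shared universe with disjoint supports.

    Emulates a pair of environments with negligible overlapping OTUs: the
    universe has 2*n_otus_each ids; template A puts all its mass on the
    first half, template B on the second half.  Mixing the pair at a
    controlled ratio then tunes the difficulty of telling them apart.
    """
    if n_otus_each < 1:
        raise ValueError("n_otus_each must be >= 1")
    half_a = make_template(n_otus_each, decay, seed)
    half_b = make_template(n_otus_each, decay, seed + 1)
    n = 2 * n_otus_each
    otu_ids = tuple(f"OTU{i + 1:04d}" for i in range(n))
    props_a = np.concatenate([half_a.proportions, np.zeros(n_otus_each)])
    props_b = np.concatenate([np.zeros(n_otus_each), half_b.proportions])
    return TemplateProfile(otu_ids, props_a), TemplateProfile(otu_ids, props_b)


def sample_library_sizes(
    n: int, target_median: int, log_sd: float = 1.0, seed: int = 0
) -> LibrarySizeDraw:
    """Log-normal library sizes rescaled so the realized median hits target.

    Sequencing depths vary by orders of magnitude within a run; a
    log-normal with log-scale spread ``log_sd`` emulates that.  The whole
    draw is multiplied by target_median / median(draw) — rescaling the
    realized sample, not the theoretical median — then rounded and
    floored at 1 read.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if target_median < 1:
        raise ValueError("target_median must be >= 1")
    if log_sd < 0:
        raise ValueError("log_sd must be >= 0")
    rng = np.random.default_rng(seed)
    raw = np.exp(rng.normal(0.0, log_sd, size=n))
    raw *= target_median / np.median(raw)
    sizes = np.maximum(np.rint(raw).astype(np.int64), 1)
    return LibrarySizeDraw(sizes, target_median=int(target_median), seed=int(seed))


def make_random_tree(otu_ids, seed: int = 0) -> TreeNode:
    """Random binary rooted tree over the given leaves.

    Topology grows by sequential joining: start from two leaves and
    attach each subsequent leaf to a uniformly chosen existing edge.
    Branch lengths are i.i.d. Exponential(mean 1).  Deterministic given
    the seed (same seed -> identical Newick string).
    """
    otu_ids = list(otu_ids)
    if len(otu_ids) < 2:
        raise ValueError("need at least 2 OTUs for a tree")
    rng = np.random.default_rng(seed)

    # Edge list representation: nodes are ints, leaves carry names.
    # Join sequentially, then emit Newick recursively.
    names: dict[int, str] = {0: otu_ids[0], 1: otu_ids[1]}
    children: dict[int, list[int]] = {2: [0, 1]}
    parent: dict[int, int] = {0: 2, 1: 2}
    root = 2
    next_id = 3
    edges = [0, 1]  # nodes whose parent edge can be split
    for name in otu_ids[2:]:
        edge_child = edges[int(rng.integers(len(edges)))]
        leaf, internal = next_id, next_id + 1
        next_id += 2
        names[leaf] = name
        old_parent = parent[edge_child]
        children[old_parent] = [
            internal if c == edge_child else c for c in children[old_parent]
        ]
        children[internal] = [edge_child, leaf]
        parent[internal] = old_parent
        parent[edge_child] = internal
        parent[leaf] = internal
        edges.extend([leaf, internal])

    lengths = {node: rng.exponential(1.0) for node in sorted(parent)}

    def newick(node: int) -> str:
        if node in names:
            return f"{names[node]}:{lengths[node]:.10f}"
        inner = ",".join(newick(c) for c in children[node])
        blen = f":{lengths[node]:.10f}" if node in parent else ""
        return f"({inner}){blen}"

    return TreeNode.read(io.StringIO(newick(root) + ";"))
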