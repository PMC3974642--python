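"""The two simulation frameworks: two-class mixing and perturbation.

Simulation A ("clustering"): two disjoint-support templates are mixed at
a controlled ratio (the effect size) in both directions, and an equal
number of samples is drawn multinomially from each mixture.  Higher
effect sizes make the two classes easier to tell apart; effect size 1
makes them identical.

Simulation B ("differential abundance"): every sample is drawn from one
template multinomial; samples are split into equal test and null
classes, and the counts of a random subset of OTUs are multiplied by the
effect size in the test class only.  The perturbed set is the ground
truth for downstream test evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import LibrarySizeDraw, TemplateProfile

__all__ = [
    "CountMatrix",
    "ExperimentDesign",
    "mix_templates",
    "simulate_experiment_A",
    "pick_perturbed_otus",
    "simulate_experiment_B",
]

TEST_CLASS = "test"
NULL_CLASS = "null"


@dataclass(frozen=True)
class CountMatrix:
    """Integer OTU-by-sample abundance table ("OTU table")."""

    counts: np.ndarray = field(repr=False)
    otu_ids: tuple[str, ...] = ()
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.rint(counts)):
                raise ValueError("counts must be integers")
            counts = np.rint(counts).astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D (OTUs x samples)")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "otu_ids", tuple(self.otu_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if len(self.otu_ids) != counts.shape[0]:
            raise ValueError("otu_ids length mismatch")
        if len(self.sample_ids) != counts.shape[1]:
            raise ValueError("sample_ids length mismatch")

    @property
    def library_sizes(self) -> np.ndarray:
        """Column sums: total reads per sample."""
        return self.counts.sum(axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.otu_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.to_numpy(), tuple(map(str, df.index)), tuple(map(str, df.columns)))

    def select_samples(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        return CountMatrix(
            self.counts[:, keep],
            self.otu_ids,
            tuple(np.asarray(self.sample_ids, dtype=object)[keep]),
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().rename_axis("otu_id").to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "CountMatrix":
        return cls.from_dataframe(pd.read_csv(path, sep="\t", index_col=0))

    def write_biom_json(self, path) -> None:
        """Minimal sparse BIOM v1 (JSON) writer."""
        rows, cols = np.nonzero(self.counts)
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "otubench",
            "date": "",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": list(self.shape),
            "rows": [{"id": o, "metadata": None} for o in self.otu_ids],
            "columns": [{"id": s, "metadata": None} for s in self.sample_ids],
            "data": [
                [int(r), int(c), int(self.counts[r, c])] for r, c in zip(rows, cols)
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def read_biom_json(cls, path) -> "CountMatrix":
        with open(path) as fh:
            doc = json.load(fh)
        counts = np.zeros(doc["shape"], dtype=np.int64)
        if doc["matrix_type"] == "sparse":
            for r, c, v in doc["data"]:
                counts[r, c] = v
        else:
            counts = np.asarray(doc["data"], dtype=np.int64)
        return cls(
            counts,
            tuple(r["id"] for r in doc["rows"]),
            tuple(c["id"] for c in doc["columns"]),
        )


@dataclass(frozen=True)
class ExperimentDesign:
    """Per-sample class labels plus the ground truth of a simulation."""

    class_of_sample: tuple[str, ...]
    effect_size: float = 1.0
    perturbed_otus: frozenset = frozenset()
    sim_kind: str = "A"

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_of_sample", tuple(self.class_of_sample))
        object.__setattr__(self, "perturbed_otus", frozenset(self.perturbed_otus))
        levels = set(self.class_of_sample)
        if len(levels) != 2:
            raise ValueError("design must have exactly two class levels")
        if self.sim_kind not in ("A", "B"):
            raise ValueError("sim_kind must be 'A' or 'B'")
        if self.sim_kind == "A" and self.perturbed_otus:
            raise ValueError("Simulation A has no perturbed OTUs")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if self.sim_kind == "B":
            counts = [self.class_of_sample.count(lv) for lv in sorted(levels)]
            if counts[0] != counts[1]:
                raise ValueError("Simulation B classes must be equal size")

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(self.class_of_sample, dtype=object)

    def mask(self, level: str) -> np.ndarray:
        return self.labels == level

    def write_tsv(self, path, sample_ids) -> None:
        pd.DataFrame(
            {"sample_id": list(sample_ids), "class": list(self.class_of_sample)}
        ).to_csv(path, sep="\t", index=False)


def mix_templates(
    target: TemplateProfile, other: TemplateProfile, effect_size: float
) -> TemplateProfile:
    """Mix two templates so target:other mass ratio equals the effect size.

    q_i is proportional to effect_size*target_i + other_i, renormalized.
    effect_size 1 gives the symmetric average (classes indistinguishable);
    effect_size -> infinity converges to the target profile.
    """
    if target.otu_ids != other.otu_ids:
        raise ValueError("templates must share the same OTU universe")
    if effect_size < 1:
        raise ValueError("effect_size must be >= 1")
    q = effect_size * target.proportions + other.proportions
    return TemplateProfile(target.otu_ids, q / q.sum())


def _draw_counts(
    proportions: np.ndarray, sizes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    return np.column_stack(
        [rng.multinomial(int(s), proportions) for s in sizes]
    )


def simulate_experiment_A(
    template_pair: tuple[TemplateProfile, TemplateProfile],
    library_sizes: LibrarySizeDraw,
    effect_size: float,
    n_per_class: int = 40,
    seed: int = 0,
) -> tuple[CountMatrix, ExperimentDesign]:
    """Two-class mixing experiment for the clustering benchmark.

    Class 1 samples are Multinomial(s_j, mix(A, B, ES)); class 2 samples
    are Multinomial(s_j, mix(B, A, ES)).  Column sums equal the supplied
    library sizes exactly.
    """
    a, b = template_pair
    if library_sizes.n != 2 * n_per_class:
        raise ValueError("library_sizes must have 2*n_per_class entries")
    rng = np.random.default_rng(seed)
    mix_1 = mix_templates(a, b, effect_size)
    mix_2 = mix_templates(b, a, effect_size)
    sizes = library_sizes.sizes
    counts = np.concatenate(
        [
            _draw_counts(mix_1.proportions, sizes[:n_per_class], rng),
            _draw_counts(mix_2.proportions, sizes[n_per_class:], rng),
        ],
        axis=1,
    )
    sample_ids = tuple(f"S{i + 1:03d}" for i in range(2 * n_per_class))
    labels = ("class1",) * n_per_class + ("class2",) * n_per_class
    design = ExperimentDesign(labels, effect_size=effect_size, sim_kind="A")
    return CountMatrix(counts, a.otu_ids, sample_ids), design


def pick_perturbed_otus(
    template: TemplateProfile, fraction: float = 0.10, seed: int = 0
) -> frozenset:
    """Uniformly random OTU subset of size round(fraction * n_otus)."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    size = int(round(fraction * template.n_otus))
    if size < 1:
        raise ValueError("fraction selects no OTUs")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(template.n_otus, size=size, replace=False)
    return frozenset(template.otu_ids[i] for i in chosen)


def simulate_experiment_B(
    template: TemplateProfile,
    library_sizes: LibrarySizeDraw,
    effect_size: float,
    perturbed_otus: frozenset,
    n_per_class: int = 10,
    seed: int = 0,
    perturb_proportions: bool = False,
) -> tuple[CountMatrix, ExperimentDesign]:
    """Single-template perturbation experiment for differential abundance.

    All samples are multinomial draws from the template; counts of the
    perturbed OTUs in test-class samples are then multiplied by the
    effect size (rounded to integers), inflating those samples' library
    sizes — the default, matching perturbation of observed counts.  With
    ``perturb_proportions=True`` the effect is instead applied to the
    template proportions (renormalized) before sampling, keeping column
    sums equal to the drawn library sizes; provided for sensitivity
    analysis.
    """
    if library_sizes.n != 2 * n_per_class:
        raise ValueError("library_sizes must have 2*n_per_class entries")
    if library_sizes.n % 2:
        raise ValueError("total sample count must be even")
    perturbed_otus = frozenset(perturbed_otus)
    if not perturbed_otus <= set(template.otu_ids):
        raise ValueError("perturbed_otus must be a subset of the template's OTUs")
    rng = np.random.default_rng(seed)
    sizes = library_sizes.sizes
    pert_idx = np.array(
        [i for i, o in enumerate(template.otu_ids) if o in perturbed_otus], dtype=int
    )
    if perturb_proportions:
        props_test = template.proportions.copy()
        props_test[pert_idx] *= effect_size
        props_test /= props_test.sum()
        test = _draw_counts(props_test, sizes[:n_per_class], rng)
        null = _draw_counts(template.proportions, sizes[n_per_class:], rng)
        counts = np.concatenate([test, null], axis=1)
    else:
        counts = _draw_counts(template.proportions, sizes, rng)
        block = counts[np.ix_(pert_idx, np.arange(n_per_class))]
        counts[np.ix_(pert_idx, np.arange(n_per_class))] = np.rint(
            block * float(effect_size)
        ).astype(np.int64)
    sample_ids = tuple(f"S{i + 1:03d}" for i in range(2 * n_per_class))
    labels = (TEST_CLASS,) * n_per_class + (NULL_CLASS,) * n_per_class
    design = ExperimentDesign(
        labels,
        effect_size=effect_size,
        perturbed_otus=perturbed_otus,
        sim_kind="B",
    )
    return CountMatrix(counts, template.otu_ids, sample_ids), design
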