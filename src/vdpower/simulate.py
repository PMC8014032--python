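"""Synthetic genotype populations with controlled variety structure.

The study design behind the acceptance surface is a grid of 84 statistical
populations (four data arrays x 21 rows), each of 206 samples typed at 10
four-allele SNP loci. A row specifies D singleton varieties plus T repeated
groups of R identical samples (D + R*T = 206 throughout). Array 1 grows a
single repeated group (convergence toward one variety); arrays 2-4 grow the
number of repeated groups at fixed sizes 2, 5 and 10 (convergence toward
many varieties).

Two distinctness regimes control how different the variety genotypes are:

* ``all_loci`` — any two varieties differ at every locus. A four-allele
  locus offers C(4,2)+4 = 10 unordered diploid classes, so at most 10
  varieties fit; this regime pins the per-locus class spectrum (e.g. the
  205/206 vs 1/206 split of the terminal array-1 population) that the
  total-discrimination-power value depends on.
* ``at_least_one`` — varieties get unique 10-locus vectors (>=1 differing
  locus). Capacity is effectively unlimited and the partition-based indices,
  which depend only on group structure, are unaffected by the choice.

``distinctness='auto'`` (the default) uses ``all_loci`` whenever the
variety count permits and falls back to ``at_least_one`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .errors import CapacityError
from .genotype_io import GenotypeMatrix, subset_loci

__all__ = [
    "PopulationSpec",
    "table1_specs",
    "make_population",
    "inject_missing",
    "nested_subsets",
    "SNP_ALLELES",
    "GENOTYPE_CLASSES",
]

SNP_ALLELES = ("A", "C", "G", "T")

#: The 10 unordered diploid genotype classes over four alleles.
GENOTYPE_CLASSES = tuple(
    "/".join(pair) for pair in combinations_with_replacement(SNP_ALLELES, 2)
)


@dataclass(frozen=True)
class PopulationSpec:
    """Group structure of one simulated population.

    D singleton varieties plus T repeated groups of R identical samples,
    over ``n_loci`` loci with ``alleles_per_locus`` allelic states each.
    """

    array_id: int
    row_no: int
    D: int
    R: int
    T: int
    m: int = 206
    n_loci: int = 10
    alleles_per_locus: int = 4

    def __post_init__(self):
        if self.D + self.R * self.T != self.m:
            raise ValueError(
                f"inconsistent spec: D + R*T = {self.D + self.R * self.T} != m = {self.m}"
            )

    @property
    def n_varieties(self) -> int:
        return self.D + self.T


# Design grid, transcribed verbatim: 21 rows of (D, R, T) per array.
_TABLE1 = {
    1: [
        (204, 2, 1), (196, 10, 1), (186, 20, 1), (176, 30, 1), (166, 40, 1),
        (156, 50, 1), (146, 60, 1), (136, 70, 1), (126, 80, 1), (116, 90, 1),
        (106, 100, 1), (96, 110, 1), (86, 120, 1), (76, 130, 1), (66, 140, 1),
        (56, 150, 1), (46, 160, 1), (36, 170, 1), (26, 180, 1), (16, 190, 1),
        (1, 205, 1),
    ],
    2: [
        (204, 2, 1), (196, 2, 5), (186, 2, 10), (176, 2, 15), (166, 2, 20),
        (156, 2, 25), (146, 2, 30), (136, 2, 35), (126, 2, 40), (116, 2, 45),
        (106, 2, 50), (96, 2, 55), (86, 2, 60), (76, 2, 65), (66, 2, 70),
        (56, 2, 75), (46, 2, 80), (36, 2, 85), (26, 2, 90), (16, 2, 95),
        (6, 2, 100),
    ],
    3: [
        (201, 5, 1), (196, 5, 2), (186, 5, 4), (176, 5, 6), (166, 5, 8),
        (156, 5, 10), (146, 5, 12), (136, 5, 14), (126, 5, 16), (116, 5, 18),
        (106, 5, 20), (96, 5, 22), (86, 5, 24), (76, 5, 26), (66, 5, 28),
        (56, 5, 30), (46, 5, 32), (36, 5, 34), (26, 5, 36), (16, 5, 38),
        (6, 5, 40),
    ],
    4: [
        (206, 10, 0), (196, 10, 1), (186, 10, 2), (176, 10, 3), (166, 10, 4),
        (156, 10, 5), (146, 10, 6), (136, 10, 7), (126, 10, 8), (116, 10, 9),
        (106, 10, 10), (96, 10, 11), (86, 10, 12), (76, 10, 13), (66, 10, 14),
        (56, 10, 15), (46, 10, 16), (36, 10, 17), (26, 10, 18), (16, 10, 19),
        (6, 10, 20),
    ],
}


def table1_specs(array_id: int) -> list[PopulationSpec]:
    """The 21 population specifications of one data array (1..4)."""
    if array_id not in _TABLE1:
        raise ValueError(f"array_id must be 1..4, got {array_id}")
    return [
        PopulationSpec(array_id, row_no, D, R, T)
        for row_no, (D, R, T) in enumerate(_TABLE1[array_id], start=1)
    ]


def _variety_vectors(spec: PopulationSpec, rng: np.random.Generator, distinctness: str):
    """Class-index vectors (n_varieties x n_loci), pairwise distinct per regime."""
    n_var, n_loci = spec.n_varieties, spec.n_loci
    n_classes = len(GENOTYPE_CLASSES)
    if distinctness == "all_loci":
        if n_var > n_classes:
            raise CapacityError(
                f"all_loci distinctness supports at most {n_classes} varieties "
                f"({n_classes} diploid classes per four-allele locus); spec has {n_var}"
            )
        # a fresh permutation per locus: variety v takes class perm[v], so any
        # two varieties differ at every locus
        return np.stack(
            [rng.permutation(n_classes)[:n_var] for _ in range(n_loci)], axis=1
        )
    if distinctness != "at_least_one":
        raise ValueError(f"unknown distinctness regime {distinctness!r}")
    vectors = rng.integers(0, n_classes, size=(n_var, n_loci))
    # resample duplicate vectors until all 10-locus profiles are unique
    while True:
        _, first = np.unique(vectors, axis=0, return_index=True)
        dup = np.setdiff1d(np.arange(n_var), first)
        if dup.size == 0:
            return vectors
        vectors[dup] = rng.integers(0, n_classes, size=(dup.size, n_loci))


def make_population(
    spec: PopulationSpec, seed: int, distinctness: str = "auto"
) -> GenotypeMatrix:
    """Simulate one population: D singletons plus T groups of R identical samples.

    Deterministic given ``seed``. Sample order is shuffled so group
    membership is not recoverable from row position.
    """
    rng = np.random.default_rng(seed)
    if distinctness == "auto":
        distinctness = "all_loci" if spec.n_varieties <= len(GENOTYPE_CLASSES) else "at_least_one"
    vectors = _variety_vectors(spec, rng, distinctness)

    variety_of_sample = np.concatenate(
        [np.arange(spec.D)] + [np.full(spec.R, spec.D + g) for g in range(spec.T)]
    ).astype(int)
    rng.shuffle(variety_of_sample)

    classes = np.array(GENOTYPE_CLASSES, dtype=object)
    grid = classes[vectors[variety_of_sample]]
    width = len(str(spec.m))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(spec.m)]
    locus_ids = [f"L{j + 1}" for j in range(spec.n_loci)]
    frame = pd.DataFrame(grid, index=sample_ids, columns=locus_ids)
    return GenotypeMatrix(frame, marker_type="SNP")


def inject_missing(matrix: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Mask a fixed per-sample quota of calls as missing.

    Every sample loses exactly round(rate * n_loci) calls at positions drawn
    uniformly without replacement; deterministic given ``seed``. The input
    matrix is unchanged.
    """
    if not 0 <= rate < 1:
        raise ValueError(f"missing rate must be in [0, 1), got {rate}")
    quota = int(np.floor(rate * matrix.n_loci + 0.5))
    frame = matrix.frame
    if quota == 0:
        return GenotypeMatrix(frame, marker_type=matrix.marker_type)
    rng = np.random.default_rng(seed)
    values = frame.to_numpy(dtype=object)
    for i in range(matrix.n_samples):
        hit = rng.choice(matrix.n_loci, size=quota, replace=False)
        values[i, hit] = None
    return GenotypeMatrix(
        pd.DataFrame(values, index=frame.index, columns=frame.columns),
        marker_type=matrix.marker_type,
    )


def nested_subsets(matrix: GenotypeMatrix, sizes, seed: int) -> list[GenotypeMatrix]:
    """Nested chain of locus subsets of the given strictly descending sizes.

    One random locus order is drawn from ``seed`` and truncated to each
    size, so every subset's locus set contains the next smaller one.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("sizes must be non-empty")
    if any(b >= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError(f"sizes must be strictly descending, got {sizes}")
    if sizes[0] > matrix.n_loci or sizes[-1] < 1:
        raise ValueError(
            f"sizes must lie in [1, {matrix.n_loci}] for a {matrix.n_loci}-locus matrix"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(np.array(matrix.locus_ids, dtype=object)))
    return [subset_loci(matrix, order[:k]) for k in sizes]
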