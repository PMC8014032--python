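"""Loci-combination appraisal statistics.

Four indices measure how well a set of marker loci separates the varieties
present in a sample population, all on a 0..1 scale where 1 means every
variety is distinguished:

* **P-VDP** — probability that two samples drawn without replacement fall
  in different repeated groups:
  ``1 - sum_i C(R_i, 2) * T_i / C(m, 2)`` over the category table. Requires
  the perfect-match rule and complete data, because the group structure is
  otherwise not a faithful census of variety identity.
* **C-VDP** — proportion of ordered sample pairs classified as different
  varieties by global traversal: ``sum_{i != j} d_ij / (m (m - 1))``. Valid
  under any threshold and with missing data.
* **C-VDP (chain form)** — the closed form of C-VDP on a partition,
  ``1 - 2 sum_i C(R_i, 2) T_i / (m (m - 1))``; algebraically identical to
  P-VDP whenever the same-variety relation is transitive.
* **R-VDP** — number of repeated groups over number of samples, ``t / m``;
  the parsimony-style index, most sensitive but bounded below by 1/m.

The per-locus discrimination power ``DP_j = 1 - sum_k g_jk^2`` uses
genotype-class frequencies (unordered diploid pairs as classes, computed
over called samples only), and the total discrimination power combines
loci by the multiplication law ``TDP = 1 - prod_j (1 - DP_j)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

from .errors import ValidityError
from .genotype_io import GenotypeMatrix
from .grouping import Partition, ThresholdRule, build_partition
from .pairwise import difference_matrix

__all__ = [
    "LocusFrequencies",
    "IndexResult",
    "locus_frequencies",
    "locus_dp",
    "tdp",
    "p_vdp",
    "c_vdp",
    "c_vdp_chain",
    "r_vdp",
    "evaluate",
    "METHODS",
]

METHODS = ("p-vdp", "c-vdp", "r-vdp", "tdp")


@dataclass(frozen=True)
class IndexResult:
    """A single appraisal value with its provenance."""

    method: str
    value: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"{self.method} value {self.value} outside [0, 1]")


@dataclass(frozen=True)
class LocusFrequencies:
    """Per-locus genotype-class frequencies over non-missing calls.

    ``freqs[locus]`` maps each genotype class (canonical ``"a/b"`` string)
    to its fraction of the called samples at that locus; ``n_called[locus]``
    is the number of called samples.
    """

    freqs: dict
    n_called: dict


def locus_frequencies(matrix: GenotypeMatrix) -> LocusFrequencies:
    """Genotype-class frequency spectrum of every locus."""
    frame = matrix.frame
    freqs, n_called = {}, {}
    for locus in frame.columns:
        col = frame[locus].dropna()
        n_called[locus] = len(col)
        if len(col):
            freqs[locus] = (col.value_counts() / len(col)).to_dict()
        else:
            freqs[locus] = {}
    return LocusFrequencies(freqs, n_called)


def locus_dp(freqs: LocusFrequencies, locus) -> float:
    """Discrimination power of one locus: 1 - sum of squared class frequencies."""
    if locus not in freqs.freqs:
        raise KeyError(f"unknown locus id: {locus!r}")
    if freqs.n_called[locus] == 0:
        raise ValidityError(f"locus {locus!r} has no called samples; DP undefined")
    g = np.array(list(freqs.freqs[locus].values()))
    return float(1.0 - np.sum(g**2))


def tdp(matrix: GenotypeMatrix) -> IndexResult:
    """Total discrimination power: loci combined by the multiplication law."""
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    freqs = locus_frequencies(matrix)
    log_miss = 0.0
    for locus in matrix.locus_ids:
        dp = locus_dp(freqs, locus)  # raises for an all-missing locus
        # accumulate log(1 - DP) to keep precision when TDP -> 1
        log_miss += np.log1p(-dp) if dp < 1 else -np.inf
    value = float(-np.expm1(log_miss))
    return IndexResult("tdp", value, {"m": matrix.n_samples, "n_loci": matrix.n_loci})


def _same_pair_count(partition: Partition) -> int:
    """sum_i C(R_i, 2) * T_i — unordered same-group pairs."""
    return sum(comb(r, 2) * t for r, t in partition.category_table.items())


def p_vdp(partition: Partition) -> IndexResult:
    """Probability-based index from the category table (Eq. over C(m,2) draws).

    Only valid for a partition built under the perfect-match rule on
    complete data; otherwise the repeated groups do not census varieties.
    """
    if not partition.perfect_match:
        raise ValidityError(
            "the variety threshold of the probability-based index must be perfect match "
            "(count metric, M=1)"
        )
    if not partition.complete_data:
        raise ValidityError(
            "the probability-based index is not valid for loci combinations with missing data"
        )
    if partition.m < 2:
        raise ValueError("need at least 2 samples")
    value = 1.0 - _same_pair_count(partition) / comb(partition.m, 2)
    return IndexResult("p-vdp", value, {"m": partition.m, "t": partition.t})


def c_vdp_chain(partition: Partition) -> IndexResult:
    """Comparison-based index in its chain (closed) form on a partition."""
    if partition.m < 2:
        raise ValueError("need at least 2 samples")
    value = 1.0 - 2.0 * _same_pair_count(partition) / (partition.m * (partition.m - 1))
    return IndexResult("c-vdp", value, {"m": partition.m, "t": partition.t, "form": "chain"})


def c_vdp(
    matrix: GenotypeMatrix, rule: ThresholdRule, undefined_pairs: str = "error"
) -> IndexResult:
    """Comparison-based index by global traversal of all ordered pairs."""
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    table = difference_matrix(matrix)
    undefined = table.n_overlap == 0
    np.fill_diagonal(undefined, False)
    if undefined.any() and undefined_pairs == "error":
        from .errors import UndefinedComparisonError

        raise UndefinedComparisonError(table.undefined_pairs())
    if rule.metric == "count":
        different = table.n_diff >= rule.min_diff
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            different = table.n_diff / np.maximum(table.n_overlap, 1) >= rule.min_diff
    if undefined_pairs == "different":
        different |= undefined
    else:
        different &= ~undefined
    np.fill_diagonal(different, False)
    m = matrix.n_samples
    value = float(different.sum()) / (m * (m - 1))
    return IndexResult("c-vdp", value, {"m": m, "rule": (rule.metric, rule.min_diff)})


def r_vdp(partition: Partition) -> IndexResult:
    """Ratio-based index: repeated groups over samples, t / m."""
    if partition.m < 2:
        raise ValueError("need at least 2 samples")
    value = partition.t / partition.m
    return IndexResult("r-vdp", value, {"m": partition.m, "t": partition.t})


def evaluate(
    matrix: GenotypeMatrix,
    method: str,
    rule: ThresholdRule | None = None,
    undefined_pairs: str = "error",
) -> IndexResult:
    """Evaluate one appraisal method on a genotype matrix.

    ``rule`` is required for the three partition/comparison indices and
    ignored for TDP (whose genotype-frequency basis is equivalent to a
    perfect-match setting).
    """
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if method == "tdp":
        return tdp(matrix)
    if rule is None:
        raise ValidityError(f"{method} requires a threshold rule")
    if method == "c-vdp":
        return c_vdp(matrix, rule, undefined_pairs)
    partition = build_partition(matrix, rule, undefined_pairs)
    return p_vdp(partition) if method == "p-vdp" else r_vdp(partition)
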