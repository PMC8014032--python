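"""Variety-threshold classification and repeated-group partitioning.

Two samples are declared *different varieties* when their pairwise
difference reaches the threshold M (a locus count, or a fraction of
overlapping loci). Samples not separated by the threshold are merged
through the discrimination chain — if A~B and B~C are same-variety pairs
then A, B and C fall in one repeated group — so groups are the connected
components of the same-variety relation. Under the perfect-match rule
(count metric, M=1) on complete data this coincides with grouping by exact
genotype-vector identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import UndefinedComparisonError, ValidityError
from .genotype_io import GenotypeMatrix
from .pairwise import PairwiseDifference, difference_matrix

__all__ = [
    "ThresholdRule",
    "PERFECT_MATCH",
    "Partition",
    "classify_pair",
    "build_partition",
    "tabulate",
    "VarietyGrouper",
]

_POLICIES = ("error", "same", "different")


@dataclass(frozen=True)
class ThresholdRule:
    """Minimum pairwise difference at which two samples are different varieties.

    ``metric='count'``: M is an integer number of differing loci (M=1 is the
    perfect-match rule — any difference separates). ``metric='percentage'``:
    M is a fraction of overlapping loci in (0, 1].
    """

    metric: str = "count"
    min_diff: float = 1

    def __post_init__(self):
        if self.metric == "count":
            if self.min_diff != int(self.min_diff) or self.min_diff < 1:
                raise ValidityError(f"count metric needs integer M >= 1, got {self.min_diff}")
            object.__setattr__(self, "min_diff", int(self.min_diff))
        elif self.metric == "percentage":
            if not 0 < self.min_diff <= 1:
                raise ValidityError(f"percentage metric needs 0 < M <= 1, got {self.min_diff}")
        else:
            raise ValidityError(f"metric must be 'count' or 'percentage', got {self.metric!r}")

    @property
    def is_perfect_match(self) -> bool:
        return self.metric == "count" and self.min_diff == 1


PERFECT_MATCH = ThresholdRule("count", 1)


def classify_pair(
    diff: PairwiseDifference, rule: ThresholdRule, undefined_pairs: str = "error"
) -> str:
    """Classify one pair as ``'same'`` or ``'different'`` variety.

    A pair with no overlapping called locus is undefined: the default
    policy raises; ``undefined_pairs='same'|'different'`` resolves it.
    """
    if undefined_pairs not in _POLICIES:
        raise ValueError(f"undefined_pairs must be one of {_POLICIES}")
    if diff.is_undefined:
        if undefined_pairs == "error":
            raise UndefinedComparisonError([("?", "?")])
        return undefined_pairs
    if rule.metric == "count":
        return "different" if diff.n_diff >= rule.min_diff else "same"
    return "different" if diff.pct_diff >= rule.min_diff else "same"


@dataclass(frozen=True)
class Partition:
    """Repeated groups of samples with their category tabulation.

    ``groups`` are disjoint, non-empty and cover all samples. Groups of
    equal size R form a *category*; ``category_table`` maps R -> T (number
    of groups of that size). Derived quantities follow the standard
    bookkeeping: D singleton groups, t groups in total, p categories with
    R >= 2 and their group counts G_k. The flags record whether the
    partition was built under the perfect-match rule on complete data,
    which the probability-based index requires.
    """

    groups: tuple
    m: int
    perfect_match: bool = False
    complete_data: bool = False
    category_table: dict = field(init=False)

    def __post_init__(self):
        sizes = [len(g) for g in self.groups]
        if any(s == 0 for s in sizes):
            raise ValueError("empty group in partition")
        all_ids = [s for g in self.groups for s in g]
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("groups are not disjoint")
        if sum(sizes) != self.m:
            raise ValueError(f"groups cover {sum(sizes)} samples, expected m={self.m}")
        table = {}
        for s in sizes:
            table[s] = table.get(s, 0) + 1
        object.__setattr__(self, "category_table", dict(sorted(table.items())))

    @classmethod
    def from_category_table(
        cls, table: dict, perfect_match: bool = True, complete_data: bool = True
    ) -> "Partition":
        """Build an anonymous partition directly from a {R: T} category table."""
        groups, k = [], 0
        for size, count in sorted(table.items()):
            for _ in range(count):
                groups.append(frozenset(f"v{k}.{i}" for i in range(size)))
                k += 1
        m = sum(size * count for size, count in table.items())
        return cls(tuple(groups), m, perfect_match=perfect_match, complete_data=complete_data)

    @property
    def t(self) -> int:
        """Total number of repeated groups."""
        return len(self.groups)

    @property
    def D(self) -> int:
        """Number of singleton groups."""
        return self.category_table.get(1, 0)

    @property
    def p(self) -> int:
        """Number of categories whose groups contain two or more samples."""
        return sum(1 for r in self.category_table if r >= 2)

    @property
    def G(self) -> dict:
        """Group counts per category with R >= 2."""
        return {r: t for r, t in self.category_table.items() if r >= 2}


def tabulate(partition: Partition):
    """Category tabulation of a partition: ({R_i: T_i}, D, t, p, {R_k: G_k})."""
    return (partition.category_table, partition.D, partition.t, partition.p, partition.G)


class VarietyGrouper(ClusterMixin, BaseEstimator):
    """Threshold clustering of samples into repeated variety groups.

    Declares two samples the same variety when their pairwise genotype
    difference stays below the threshold, then takes connected components
    of the same-variety relation (the discrimination chain).

    Parameters
    ----------
    metric : {'count', 'percentage'}
        Whether ``min_diff`` counts differing loci or is a fraction of
        overlapping loci.
    min_diff : int or float
        Threshold M; pairs at or above it are different varieties.
    undefined_pairs : {'error', 'same', 'different'}
        Policy for pairs with no overlapping called locus.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Group index per sample, in input sample order.
    partition_ : Partition
        The repeated-group partition with its category tabulation.
    n_groups_ : int
        Number of repeated groups (t).
    """

    def __init__(self, metric: str = "count", min_diff=1, undefined_pairs: str = "error"):
        self.metric = metric
        self.min_diff = min_diff
        self.undefined_pairs = undefined_pairs

    def _rule(self) -> ThresholdRule:
        return ThresholdRule(self.metric, self.min_diff)

    def fit(self, X, y=None):
        """Partition the samples of a genotype matrix.

        ``X`` is a :class:`GenotypeMatrix` or a 2-D array-like of ``"a/b"``
        call strings (None/NaN for missing).
        """
        matrix = X if isinstance(X, GenotypeMatrix) else GenotypeMatrix.from_calls(X)
        if matrix.n_samples < 2:
            raise ValueError("need at least 2 samples to partition")
        rule = self._rule()
        if self.undefined_pairs not in _POLICIES:
            raise ValueError(f"undefined_pairs must be one of {_POLICIES}")

        table = difference_matrix(matrix)
        undefined = table.n_overlap == 0
        np.fill_diagonal(undefined, False)
        if undefined.any() and self.undefined_pairs == "error":
            raise UndefinedComparisonError(table.undefined_pairs())

        if rule.metric == "count":
            different = table.n_diff >= rule.min_diff
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                pct = table.n_diff / np.maximum(table.n_overlap, 1)
            different = pct >= rule.min_diff
        if self.undefined_pairs == "different":
            different |= undefined
        else:
            different &= ~undefined
        same = ~different
        np.fill_diagonal(same, False)

        n, labels = connected_components(csr_matrix(same), directed=False)
        self.labels_ = labels
        self.n_groups_ = int(n)
        ids = matrix.sample_ids
        groups = [frozenset(np.array(ids, dtype=object)[labels == g]) for g in range(n)]
        self.partition_ = Partition(
            tuple(groups),
            matrix.n_samples,
            perfect_match=rule.is_perfect_match,
            complete_data=matrix.is_complete,
        )
        return self


def build_partition(
    matrix: GenotypeMatrix, rule: ThresholdRule, undefined_pairs: str = "error"
) -> Partition:
    """Partition samples into repeated groups under a threshold rule."""
    grouper = VarietyGrouper(rule.metric, rule.min_diff, undefined_pairs)
    return grouper.fit(matrix).partition_
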