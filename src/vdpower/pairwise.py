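"""Pairwise variety-difference degree between samples.

For a pair of samples the difference is computed over the *overlapping*
loci — those called (non-missing) in both samples. A locus counts as
different iff the unordered allele pairs are unequal; there is no partial
credit for sharing one allele of a heterozygote. Pairs with no overlapping
locus have an undefined difference and are flagged rather than scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

__all__ = ["PairwiseDifference", "DifferenceTable", "pair_difference", "difference_matrix"]


@dataclass(frozen=True)
class PairwiseDifference:
    """Difference degree of one unordered sample pair.

    ``n_diff`` loci differ out of ``n_overlap`` loci called in both samples.
    """

    n_diff: int
    n_overlap: int

    def __post_init__(self):
        if not 0 <= self.n_diff <= self.n_overlap:
            raise ValueError(f"invalid pair counts: n_diff={self.n_diff}, n_overlap={self.n_overlap}")

    @property
    def is_undefined(self) -> bool:
        """True when the samples share no called locus."""
        return self.n_overlap == 0

    @property
    def pct_diff(self) -> float | None:
        """Fraction of overlapping loci that differ; None when undefined."""
        if self.n_overlap == 0:
            return None
        return self.n_diff / self.n_overlap


class DifferenceTable:
    """Symmetric table of pairwise differences over all unordered pairs."""

    def __init__(self, sample_ids, n_diff: np.ndarray, n_overlap: np.ndarray):
        self.sample_ids = list(sample_ids)
        self.n_diff = n_diff
        self.n_overlap = n_overlap
        self._pos = {s: k for k, s in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_pairs(self) -> int:
        m = self.n_samples
        return m * (m - 1) // 2

    def get(self, i, j) -> PairwiseDifference:
        if i == j:
            raise ValueError(f"a sample is never compared with itself ({i!r})")
        try:
            a, b = self._pos[i], self._pos[j]
        except KeyError as exc:
            raise KeyError(f"unknown sample id: {exc.args[0]!r}")
        return PairwiseDifference(int(self.n_diff[a, b]), int(self.n_overlap[a, b]))

    def undefined_pairs(self) -> list:
        """Unordered id pairs with zero overlapping called loci."""
        a, b = np.nonzero(np.triu(self.n_overlap == 0, k=1))
        return [(self.sample_ids[i], self.sample_ids[j]) for i, j in zip(a, b)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: sample_i, sample_j, n_diff, n_overlap, pct_diff."""
        ii, jj = np.triu_indices(self.n_samples, k=1)
        overlap = self.n_overlap[ii, jj]
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(overlap > 0, self.n_diff[ii, jj] / np.maximum(overlap, 1), np.nan)
        return pd.DataFrame(
            {
                "sample_i": [self.sample_ids[i] for i in ii],
                "sample_j": [self.sample_ids[j] for j in jj],
                "n_diff": self.n_diff[ii, jj],
                "n_overlap": overlap,
                "pct_diff": pct,
            }
        )


def _pairwise_counts(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate per-pair difference and overlap counts one locus at a time.

    Keeps memory at O(m^2) rather than O(m^2 * loci).
    """
    m = codes.shape[0]
    n_diff = np.zeros((m, m), dtype=np.int64)
    n_overlap = np.zeros((m, m), dtype=np.int64)
    for j in range(codes.shape[1]):
        col = codes[:, j]
        called = col >= 0
        both = called[:, None] & called[None, :]
        n_overlap += both
        n_diff += both & (col[:, None] != col[None, :])
    np.fill_diagonal(n_diff, 0)
    np.fill_diagonal(n_overlap, 0)
    return n_diff, n_overlap


def difference_matrix(matrix: GenotypeMatrix) -> DifferenceTable:
    """All-pairs difference table (global traversal over unordered pairs)."""
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to compare")
    n_diff, n_overlap = _pairwise_counts(matrix.codes())
    return DifferenceTable(matrix.sample_ids, n_diff, n_overlap)


def pair_difference(matrix: GenotypeMatrix, i, j) -> PairwiseDifference:
    """Difference degree between samples ``i`` and ``j``.

    Loci missing in either sample are excluded from numerator and
    denominator alike.
    """
    if i == j:
        raise ValueError(f"a sample is never compared with itself ({i!r})")
    ids = matrix.sample_ids
    for s in (i, j):
        if s not in ids:
            raise KeyError(f"unknown sample id: {s!r}")
    codes = matrix.codes()
    a, b = codes[ids.index(i)], codes[ids.index(j)]
    both = (a >= 0) & (b >= 0)
    return PairwiseDifference(int(((a != b) & both).sum()), int(both.sum()))
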