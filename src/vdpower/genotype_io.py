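"""Reading, writing and subsetting codominant genotype matrices.

A genotype matrix is a samples × loci table of unordered diploid allele
pairs (SSR fragment sizes or SNP bases) with an explicit missing state.
Allele labels are opaque strings: the discrimination statistics only ever
ask whether two calls are equal, so SSR sizes are never parsed numerically.

The canonical cell encoding is ``"a/b"`` with the two allele labels in
sorted order, or :data:`None` for a missing call; heterozygote order in the
input is irrelevant (``A/T`` and ``T/A`` are the same call).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "MISSING",
    "Dialect",
    "DEFAULT_DIALECT",
    "GenotypeCall",
    "GenotypeMatrix",
    "read_genotypes",
    "write_genotypes",
    "subset_loci",
]

#: Sentinel for a missing genotype call.
MISSING = None

#: Name of the leading sample-identifier column in delimited files.
SAMPLE_COLUMN = "sample"


@dataclass(frozen=True)
class Dialect:
    """Layout of a delimited genotype file.

    Parameters
    ----------
    delimiter
        Field separator, tab by default.
    missing_code
        Token written (and recognised) for a missing call. A call is also
        missing when either allele field is empty.
    pair_sep
        Separator joining the two alleles within one cell (single-column
        layout only).
    two_column
        If true, each locus occupies two adjacent columns named
        ``<locus>_1`` and ``<locus>_2`` instead of one ``a/b`` column.
    """

    delimiter: str = "\t"
    missing_code: str = "NA"
    pair_sep: str = "/"
    two_column: bool = False


DEFAULT_DIALECT = Dialect()


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered diploid allele pair, or the missing call.

    ``alleles`` is a sorted 2-tuple of allele labels, or ``None`` when the
    call is missing. Construction canonicalises order, so
    ``GenotypeCall(("T", "A")) == GenotypeCall(("A", "T"))``.
    """

    alleles: tuple[str, str] | None

    def __post_init__(self):
        if self.alleles is not None:
            a, b = self.alleles
            object.__setattr__(self, "alleles", tuple(sorted((str(a), str(b)))))

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    def encode(self, dialect: Dialect = DEFAULT_DIALECT) -> str:
        if self.alleles is None:
            return dialect.missing_code
        return dialect.pair_sep.join(self.alleles)


def _canonical(a: str, b: str) -> str:
    """Canonical string form of a call: sorted alleles joined by '/'."""
    return "/".join(sorted((a, b)))


class GenotypeMatrix:
    """Samples × loci grid of unordered diploid calls with a missing mask.

    Backed by a pandas DataFrame of canonical ``"a/b"`` strings
    (``None`` for missing) indexed by sample id with locus-id columns.
    """

    def __init__(self, calls: pd.DataFrame, marker_type: str = "SNP"):
        if calls.index.has_duplicates:
            dup = calls.index[calls.index.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if calls.columns.has_duplicates:
            dup = calls.columns[calls.columns.duplicated()][0]
            raise FormatError(f"duplicate locus id: {dup!r}")
        if marker_type not in ("SNP", "SSR"):
            raise FormatError(f"marker_type must be 'SNP' or 'SSR', got {marker_type!r}")
        self._calls = calls
        self.marker_type = marker_type

    # -- construction ----------------------------------------------------

    @classmethod
    def from_calls(
        cls,
        calls,
        sample_ids=None,
        locus_ids=None,
        marker_type: str = "SNP",
    ) -> "GenotypeMatrix":
        """Build a matrix from a 2-D array-like of call strings.

        Cells may be ``"a/b"`` strings (any allele order), ``None``/NaN for
        missing, or :class:`GenotypeCall` objects. Ids default to
        ``S1..Sm`` / ``L1..Ln``.
        """
        arr = np.asarray(calls, dtype=object)
        if arr.ndim != 2:
            raise FormatError("calls must be a 2-D grid")
        m, n = arr.shape
        sample_ids = [f"S{i + 1}" for i in range(m)] if sample_ids is None else list(sample_ids)
        locus_ids = [f"L{j + 1}" for j in range(n)] if locus_ids is None else list(locus_ids)
        out = np.empty((m, n), dtype=object)
        for i in range(m):
            for j in range(n):
                cell = arr[i, j]
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    out[i, j] = MISSING
                elif isinstance(cell, GenotypeCall):
                    out[i, j] = MISSING if cell.is_missing else "/".join(cell.alleles)
                else:
                    parts = str(cell).split("/")
                    if len(parts) != 2 or not all(parts):
                        raise FormatError(
                            f"unparseable call {cell!r} at sample {sample_ids[i]!r}, "
                            f"locus {locus_ids[j]!r}"
                        )
                    out[i, j] = _canonical(*parts)
        frame = pd.DataFrame(out, index=sample_ids, columns=locus_ids)
        return cls(frame, marker_type=marker_type)

    # -- basic introspection ---------------------------------------------

    @property
    def sample_ids(self) -> list:
        return list(self._calls.index)

    @property
    def locus_ids(self) -> list:
        return list(self._calls.columns)

    @property
    def n_samples(self) -> int:
        return self._calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self._calls.shape[1]

    @property
    def frame(self) -> pd.DataFrame:
        """Copy of the underlying canonical-string DataFrame."""
        return self._calls.copy()

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self._calls.isna()

    @property
    def is_complete(self) -> bool:
        return not self._calls.isna().any().any()

    def call(self, sample, locus) -> GenotypeCall:
        try:
            cell = self._calls.at[sample, locus]
        except KeyError:
            raise KeyError(f"unknown sample or locus: ({sample!r}, {locus!r})")
        if pd.isna(cell):
            return GenotypeCall(None)
        return GenotypeCall(tuple(cell.split("/")))

    def codes(self) -> np.ndarray:
        """Integer-encode calls per locus: equal calls share a code, missing is -1.

        The encoding is locus-local; codes are only comparable within a column.
        """
        m, n = self._calls.shape
        out = np.full((m, n), -1, dtype=np.int64)
        for j, col in enumerate(self._calls.columns):
            codes, _ = pd.factorize(self._calls[col], use_na_sentinel=True)
            out[:, j] = codes
        return out

    # -- subsetting ------------------------------------------------------

    def subset_loci(self, keep) -> "GenotypeMatrix":
        keep = list(keep)
        if not keep:
            raise ValueError("keep must be a non-empty list of locus ids")
        if len(set(keep)) != len(keep):
            raise ValueError("keep contains duplicate locus ids")
        unknown = [k for k in keep if k not in self._calls.columns]
        if unknown:
            raise KeyError(f"unknown locus id(s): {unknown}")
        # preserve the matrix's own column order for stable output
        ordered = [c for c in self._calls.columns if c in set(keep)]
        return GenotypeMatrix(self._calls[ordered].copy(), marker_type=self.marker_type)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.marker_type == other.marker_type
            and self._calls.index.equals(other._calls.index)
            and self._calls.columns.equals(other._calls.columns)
            and self._calls.fillna("\0").equals(other._calls.fillna("\0"))
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_samples} samples x {self.n_loci} loci, "
            f"{self.marker_type}, {int(self._calls.isna().sum().sum())} missing)"
        )


def _parse_cell(cell: str, dialect: Dialect, row_label, col_label):
    cell = cell.strip()
    if cell == dialect.missing_code or cell == "":
        return MISSING
    parts = cell.split(dialect.pair_sep)
    if len(parts) != 2 or not all(p.strip() for p in parts):
        raise FormatError(
            f"unparseable call {cell!r} at sample {row_label!r}, locus {col_label!r} "
            f"(expected two alleles joined by {dialect.pair_sep!r}, "
            f"or the missing code {dialect.missing_code!r})"
        )
    return _canonical(parts[0].strip(), parts[1].strip())


def read_genotypes(path, dialect: Dialect = DEFAULT_DIALECT, marker_type: str = "SNP") -> GenotypeMatrix:
    """Read a delimited genotype table.

    The first column holds sample ids; remaining columns hold loci (one
    ``a/b`` column per locus, or two allele columns per locus when
    ``dialect.two_column``). A header row is required.
    """
    with open(path, newline="") as handle:
        rows = list(csv.reader(handle, delimiter=dialect.delimiter))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    if not header:
        raise FormatError(f"{path}: empty header row")
    body = rows[1:]
    width = len(header)
    for lineno, row in enumerate(body, start=2):
        if len(row) != width:
            raise FormatError(
                f"{path}: line {lineno} has {len(row)} fields, expected {width} (ragged row)"
            )

    if dialect.two_column:
        locus_cols = header[1:]
        if len(locus_cols) % 2:
            raise FormatError(f"{path}: odd number of allele columns in two-column layout")
        locus_ids = []
        for k in range(0, len(locus_cols), 2):
            a, b = locus_cols[k], locus_cols[k + 1]
            base_a = a[:-2] if a.endswith("_1") else a
            base_b = b[:-2] if b.endswith("_2") else b
            if base_a != base_b:
                raise FormatError(
                    f"{path}: allele columns {a!r} and {b!r} do not form a <locus>_1/<locus>_2 pair"
                )
            locus_ids.append(base_a)
    else:
        locus_ids = header[1:]

    sample_ids, grid = [], []
    for row in body:
        sid = row[0].strip()
        sample_ids.append(sid)
        cells = []
        if dialect.two_column:
            for k, locus in enumerate(locus_ids):
                a, b = row[1 + 2 * k].strip(), row[2 + 2 * k].strip()
                if a in ("", dialect.missing_code) or b in ("", dialect.missing_code):
                    cells.append(MISSING)
                else:
                    cells.append(_canonical(a, b))
        else:
            for locus, cell in zip(locus_ids, row[1:]):
                cells.append(_parse_cell(cell, dialect, sid, locus))
        grid.append(cells)

    frame = pd.DataFrame(
        np.array(grid, dtype=object).reshape(len(sample_ids), len(locus_ids)),
        index=sample_ids,
        columns=locus_ids,
    )
    return GenotypeMatrix(frame, marker_type=marker_type)


def write_genotypes(matrix: GenotypeMatrix, path, dialect: Dialect = DEFAULT_DIALECT) -> None:
    """Write a matrix so that :func:`read_genotypes` with the same dialect
    reproduces it exactly; allele pairs are emitted in canonical sorted order."""
    frame = matrix.frame
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter=dialect.delimiter, lineterminator="\n")
        if dialect.two_column:
            header = [SAMPLE_COLUMN]
            for locus in frame.columns:
                header += [f"{locus}_1", f"{locus}_2"]
            writer.writerow(header)
            for sid, row in frame.iterrows():
                out = [sid]
                for cell in row:
                    if pd.isna(cell):
                        out += [dialect.missing_code, dialect.missing_code]
                    else:
                        out += cell.split("/")
                writer.writerow(out)
        else:
            writer.writerow([SAMPLE_COLUMN] + list(frame.columns))
            for sid, row in frame.iterrows():
                out = [sid] + [
                    dialect.missing_code if pd.isna(c) else c.replace("/", dialect.pair_sep)
                    for c in row
                ]
                writer.writerow(out)


def subset_loci(matrix: GenotypeMatrix, keep) -> GenotypeMatrix:
    """Restrict ``matrix`` to the loci in ``keep`` (sample order preserved)."""
    return matrix.subset_loci(keep)
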