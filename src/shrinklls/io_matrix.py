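"""Tab-delimited gene expression matrix I/O with explicit missingness masks.

The on-disk dialect is the plain TSV layout ubiquitous in microarray work:
a header row of condition labels, a first column of gene identifiers, and
one real-valued cell per (gene, condition).  Missing entries are encoded by
an empty cell or a token such as ``NA``/``NaN`` (matched case-insensitively
on read; ``NA`` is written).

In memory a matrix is an :class:`ExpressionMatrix`: a dense double-precision
value array paired with a boolean mask that is ``True`` exactly where the
entry is missing.  Masked positions hold ``nan`` so that accidental reads
poison downstream arithmetic instead of silently using a stale number.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

DEFAULT_MISSING_TOKENS = frozenset({"", "na", "nan"})


class MatrixFormatError(ValueError):
    """Structural problem in a matrix file (ragged rows, bad header)."""


class MatrixParseError(ValueError):
    """A cell that is neither a finite real nor a missing token."""


class MatrixValidationError(ValueError):
    """An in-memory matrix violating the container invariants."""


@dataclass
class ExpressionMatrix:
    """An m-gene x n-condition expression matrix with a missingness mask.

    Attributes
    ----------
    gene_ids:
        Unique row identifiers, length ``m``.
    condition_ids:
        Column labels (experimental conditions or time points), length ``n``.
    values:
        ``(m, n)`` float64 array of (log-)expression values.  Positions
        flagged missing hold ``nan``.
    missing_mask:
        ``(m, n)`` boolean array, ``True`` where the entry is missing.
    """

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.validate()
        # Masked slots must never contribute a meaningful number.
        self.values = np.where(self.missing_mask, np.nan, self.values)

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        m, n = len(self.gene_ids), len(self.condition_ids)
        if m < 1 or n < 1:
            raise MatrixValidationError(
                f"matrix must be at least 1x1, got {m} genes x {n} conditions"
            )
        if self.values.shape != (m, n):
            raise MatrixValidationError(
                f"values shape {self.values.shape} does not match "
                f"{m} genes x {n} conditions"
            )
        if self.missing_mask.shape != (m, n):
            raise MatrixValidationError(
                f"missing_mask shape {self.missing_mask.shape} does not match "
                f"values shape {self.values.shape}"
            )
        if len(set(self.gene_ids)) != m:
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))
            raise MatrixValidationError(f"duplicate gene ID: {dup!r}")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise MatrixValidationError("non-finite value at an observed position")

    # -- conveniences -----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            condition_ids=list(self.condition_ids),
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
        )


def read_matrix(
    path: str | Path,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    The first row is the condition header (its first cell is ignored); the
    first column holds gene IDs.  A cell equal, case-insensitively, to any
    of *missing_tokens* is recorded as missing.

    Raises
    ------
    MatrixFormatError
        On ragged rows (message names the 1-based file line).
    MatrixValidationError
        On duplicate gene IDs or an empty matrix.
    MatrixParseError
        On a cell that is neither a finite real nor a missing token
        (message names the gene row and condition column).
    """
    tokens = {t.lower() for t in missing_tokens}
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [row for row in reader if row]  # skip blank lines
    if not rows:
        raise MatrixFormatError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 2:
        raise MatrixFormatError(f"{path}: header row has no condition columns")
    condition_ids = [c.strip() for c in header[1:]]
    n = len(condition_ids)

    gene_ids: list[str] = []
    values = np.empty((len(rows) - 1, n), dtype=np.float64)
    mask = np.zeros((len(rows) - 1, n), dtype=bool)
    for i, row in enumerate(rows[1:]):
        line_no = i + 2  # 1-based line in file, after the header
        if len(row) != n + 1:
            raise MatrixFormatError(
                f"{path}: row {line_no} has {len(row)} columns, expected {n + 1}"
            )
        gene_ids.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            text = cell.strip()
            if text.lower() in tokens:
                mask[i, j] = True
                values[i, j] = np.nan
                continue
            try:
                v = float(text)
            except ValueError:
                raise MatrixParseError(
                    f"{path}: unparseable cell {text!r} at gene row {i + 1} "
                    f"(line {line_no}), condition column {j + 1}"
                ) from None
            if not np.isfinite(v):
                raise MatrixParseError(
                    f"{path}: non-finite value {text!r} at gene row {i + 1} "
                    f"(line {line_no}), condition column {j + 1}"
                )
            values[i, j] = v
    return ExpressionMatrix(gene_ids, condition_ids, values, mask)


def write_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    missing_token: str = "NA",
) -> None:
    """Write *matrix* as a tab-delimited file, round-trippable by
    :func:`read_matrix` (values at 17 significant digits, mask exactly)."""
    matrix.validate()
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["GENE_ID", *matrix.condition_ids])
        for i, gid in enumerate(matrix.gene_ids):
            row: list[str] = [gid]
            for j in range(matrix.n_conditions):
                if matrix.missing_mask[i, j]:
                    row.append(missing_token)
                else:
                    row.append(repr(float(matrix.values[i, j])))
            writer.writerow(row)


def drop_incomplete_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Return the submatrix of genes with no missing entries, order preserved.

    Emits a warning (not an error) if every gene is incomplete; the result
    then has zero rows and bypasses the m >= 1 container invariant check.
    """
    keep = ~matrix.missing_mask.any(axis=1)
    if not keep.any():
        warnings.warn(
            "every gene has at least one missing value; result has 0 rows",
            stacklevel=2,
        )
        out = ExpressionMatrix.__new__(ExpressionMatrix)
        out.gene_ids = []
        out.condition_ids = list(matrix.condition_ids)
        out.values = matrix.values[keep].copy()
        out.missing_mask = matrix.missing_mask[keep].copy()
        return out
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(matrix.gene_ids, keep) if k],
        condition_ids=list(matrix.condition_ids),
        values=matrix.values[keep].copy(),
        missing_mask=matrix.missing_mask[keep].copy(),
    )


def matrix_from_values(
    values: Sequence[Sequence[float]] | np.ndarray,
    missing_mask: np.ndarray | None = None,
    gene_ids: Sequence[str] | None = None,
    condition_ids: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Build an :class:`ExpressionMatrix` from an array, autogenerating IDs."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2:
        raise MatrixValidationError("values must be 2-dimensional")
    m, n = arr.shape
    if missing_mask is None:
        missing_mask = np.isnan(arr)
    if gene_ids is None:
        gene_ids = [f"G{i + 1:04d}" for i in range(m)]
    if condition_ids is None:
        condition_ids = [f"C{j + 1:02d}" for j in range(n)]
    return ExpressionMatrix(list(gene_ids), list(condition_ids), arr, missing_mask)
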