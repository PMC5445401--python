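"""Tabular I/O for expression matrices, sample sheets and distance matrices.

All formats are plain UTF-8 text. Tab-separated values are the canonical
dialect; comma-separated files are accepted via ``sep=","``. Probe and array
ordering is preserved exactly as given — nothing is sorted silently.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleSheet",
    "DistanceMatrix",
    "MatrixFormatError",
    "MatrixValueError",
    "CrossValidationError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_distance_matrix",
    "write_distance_matrix",
]


class MatrixFormatError(ValueError):
    """Structural problem in a tabular input (duplicate ids, bad header...)."""


class MatrixValueError(ValueError):
    """A cell value violates an invariant; the message locates it."""


class CrossValidationError(ValueError):
    """Matrix and sample sheet disagree about the arrays present."""


_SAMPLE_SHEET_COLUMNS = (
    "array_id",
    "cell_line",
    "replicate",
    "is_reference",
    "has_ct",
    "has_nt",
)

_TRUE_STRINGS = {"true", "1", "yes", "t", "y"}
_FALSE_STRINGS = {"false", "0", "no", "f", "n"}


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise MatrixFormatError(f"duplicate {kind} identifier {i!r}")
        seen.add(i)


class ExpressionMatrix:
    """Probes x arrays intensity table.

    Intensities are arbitrary (already-normalized) fluorescence units:
    strictly finite and non-negative. Zeros are admitted at read time; the
    divide-by-zero hazard in fold-change computation is handled downstream
    by a floor (see :mod:`ohcpipe.genesets`).
    """

    def __init__(self, values: pd.DataFrame):
        probe_ids = [str(p) for p in values.index]
        array_ids = [str(a) for a in values.columns]
        _check_unique(probe_ids, "probe")
        _check_unique(array_ids, "array")
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            # locate the first offending cell for the error message
            for j, col in enumerate(values.columns):
                coerced = pd.to_numeric(values[col], errors="coerce")
                bad = coerced.isna() & values[col].notna() | values[col].isna()
                if bad.any():
                    i = int(np.argmax(bad.to_numpy()))
                    raise MatrixValueError(
                        f"non-numeric value {values.iloc[i, j]!r} at probe "
                        f"{probe_ids[i]!r}, array {array_ids[j]!r}"
                    )
            raise MatrixValueError("non-numeric values in matrix body")
        arr = arr.astype(float)
        if not np.all(np.isfinite(arr)):
            i, j = map(int, np.argwhere(~np.isfinite(arr))[0])
            raise MatrixValueError(
                f"non-finite value at probe {probe_ids[i]!r}, array {array_ids[j]!r}"
            )
        if (arr < 0).any():
            i, j = map(int, np.argwhere(arr < 0)[0])
            raise MatrixValueError(
                f"negative intensity {arr[i, j]} at probe {probe_ids[i]!r}, "
                f"array {array_ids[j]!r}"
            )
        self._frame = pd.DataFrame(arr, index=probe_ids, columns=array_ids)

    # -- accessors ---------------------------------------------------------
    @property
    def values(self) -> pd.DataFrame:
        return self._frame

    @property
    def probe_ids(self) -> list[str]:
        return list(self._frame.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._frame.shape

    def array(self, array_id: str) -> pd.Series:
        """Intensity column for one array, indexed by probe."""
        if array_id not in self._frame.columns:
            raise KeyError(f"unknown array {array_id!r}")
        return self._frame[array_id]

    def subset_arrays(self, array_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self._frame[list(array_ids)])

    @classmethod
    def from_arrays(
        cls,
        probe_ids: Sequence[str],
        array_ids: Sequence[str],
        values: np.ndarray,
    ) -> "ExpressionMatrix":
        return cls(pd.DataFrame(values, index=list(probe_ids), columns=list(array_ids)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self._frame.equals(other._frame)


@dataclass(frozen=True)
class SampleRecord:
    array_id: str
    cell_line: str
    replicate: str
    is_reference: bool
    has_ct: bool
    has_nt: bool


class SampleSheet:
    """Per-array metadata: cell line, replicate label, domain flags."""

    def __init__(self, records: Sequence[SampleRecord]):
        _check_unique([r.array_id for r in records], "array")
        self._records = list(records)

    @property
    def records(self) -> list[SampleRecord]:
        return list(self._records)

    @property
    def array_ids(self) -> list[str]:
        return [r.array_id for r in self._records]

    @property
    def cell_lines(self) -> list[str]:
        """Distinct cell lines in order of first appearance."""
        out: list[str] = []
        for r in self._records:
            if r.cell_line not in out:
                out.append(r.cell_line)
        return out

    def reference_arrays(self) -> list[str]:
        return [r.array_id for r in self._records if r.is_reference]

    def arrays_for_line(self, cell_line: str) -> list[str]:
        return [r.array_id for r in self._records if r.cell_line == cell_line]

    def record(self, array_id: str) -> SampleRecord:
        for r in self._records:
            if r.array_id == array_id:
                return r
        raise KeyError(f"unknown array {array_id!r}")

    def line_flags(self, cell_line: str) -> tuple[bool, bool, bool]:
        """(is_reference, has_ct, has_nt) for a cell line."""
        for r in self._records:
            if r.cell_line == cell_line:
                return r.is_reference, r.has_ct, r.has_nt
        raise KeyError(f"unknown cell line {cell_line!r}")

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Every array in the matrix must appear exactly once in the sheet."""
        sheet_ids = set(self.array_ids)
        missing = [a for a in matrix.array_ids if a not in sheet_ids]
        if missing:
            raise CrossValidationError(
                f"arrays present in matrix but missing from sample sheet: {missing}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self._records], columns=_SAMPLE_SHEET_COLUMNS)

    def __len__(self) -> int:
        return len(self._records)


class DistanceMatrix:
    """Square labelled matrix of pairwise distances in [0, 1]."""

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        labels = [str(x) for x in labels]
        _check_unique(labels, "label")
        values = np.asarray(values, dtype=float)
        n = len(labels)
        if values.shape != (n, n):
            raise MatrixFormatError(
                f"distance matrix shape {values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(values)):
            raise MatrixValueError("non-finite distance")
        if not np.allclose(values, values.T, atol=1e-12):
            raise MatrixValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise MatrixValueError("distance matrix diagonal is not zero")
        if values.min() < -1e-12 or values.max() > 1 + 1e-12:
            raise MatrixValueError("distance outside [0, 1]")
        values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(values, 0.0)
        self.labels = labels
        self.values = values

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangular entries in scipy's condensed ordering."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | os.PathLike, sep: str = "\t") -> ExpressionMatrix:
    """Read a probes-in-rows, arrays-in-columns intensity table.

    First column holds probe ids, header row holds array ids. Any
    non-numeric or negative cell raises :class:`MatrixValueError` naming
    the probe/array coordinates of the offending value.
    """
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if frame.columns.size == 0:
        raise MatrixFormatError(f"{path}: no array columns found")
    frame.index = frame.index.astype(str)
    numeric = pd.DataFrame(index=frame.index)
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise MatrixValueError(
                f"{path}: non-numeric value {frame[col].iloc[i]!r} at probe "
                f"{frame.index[i]!r}, array {col!r}"
            )
        numeric[col] = coerced
    return ExpressionMatrix(numeric)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | os.PathLike, sep: str = "\t"
) -> None:
    frame = matrix.values.copy()
    frame.index.name = "probe_id"
    frame.to_csv(path, sep=sep, lineterminator="\n")


def _parse_bool(value: object, column: str, row: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise MatrixValueError(
        f"cannot parse boolean {value!r} in column {column!r}, array {row!r}"
    )


def read_sample_sheet(path: str | os.PathLike, sep: str = "\t") -> SampleSheet:
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _SAMPLE_SHEET_COLUMNS if c not in frame.columns]
    if missing:
        raise MatrixFormatError(f"{path}: sample sheet missing columns {missing}")
    records = []
    for _, row in frame.iterrows():
        records.append(
            SampleRecord(
                array_id=str(row["array_id"]),
                cell_line=str(row["cell_line"]),
                replicate=str(row["replicate"]),
                is_reference=_parse_bool(row["is_reference"], "is_reference", row["array_id"]),
                has_ct=_parse_bool(row["has_ct"], "has_ct", row["array_id"]),
                has_nt=_parse_bool(row["has_nt"], "has_nt", row["array_id"]),
            )
        )
    return SampleSheet(records)


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike, sep: str = "\t") -> None:
    sheet.to_frame().to_csv(path, sep=sep, index=False, lineterminator="\n")


def read_distance_matrix(path: str | os.PathLike, sep: str = "\t") -> DistanceMatrix:
    frame = pd.read_csv(path, sep=sep, index_col=0)
    labels = [str(x) for x in frame.index]
    if [str(c) for c in frame.columns] != labels:
        raise MatrixFormatError(f"{path}: row and column labels differ")
    return DistanceMatrix(labels, frame.to_numpy(dtype=float))


def write_distance_matrix(
    dm: DistanceMatrix, path: str | os.PathLike, sep: str = "\t"
) -> None:
    """Write a square labelled distance matrix.

    Values are serialized with :func:`repr` precision so a read-back
    reproduces the matrix exactly.
    """
    frame = pd.DataFrame(dm.values, index=dm.labels, columns=dm.labels)
    frame.index.name = "label"
    frame.to_csv(path, sep=sep, float_format="%.17g", lineterminator="\n")
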