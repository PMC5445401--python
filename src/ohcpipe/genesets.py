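"""Fold-change gene-set construction against a parental reference.

Each array from a transformed cell line yields a gene set: the probes whose
intensity exceeds ``threshold`` times the probe's average intensity in the
parental (reference) arrays. Fold change is a plain ratio on the intensity
scale; a floor on the reference mean guards against division by zero. The
default rule is up-only with a strict inequality (fold change > 2); a
two-sided mode additionally admits probes with fold change < 1/threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleSheet

__all__ = [
    "GeneSet",
    "reference_profile",
    "fold_changes",
    "build_gene_set",
    "build_gene_sets",
    "write_gene_sets_tsv",
    "write_gene_sets_gmt",
    "read_gene_sets_tsv",
]

Mode = Literal["up", "two-sided"]


@dataclass(frozen=True)
class GeneSet:
    """Probes passing the fold-change rule for one array (or one line)."""

    array_id: str
    members: frozenset[str]
    threshold: float = 2.0
    mode: Mode = "up"

    def __post_init__(self) -> None:
        if self.threshold <= 1:
            raise ValueError(f"threshold must exceed 1, got {self.threshold}")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


def reference_profile(matrix: ExpressionMatrix, sheet: SampleSheet) -> pd.Series:
    """Per-probe arithmetic mean intensity over the reference (parental) arrays."""
    sheet.validate_against(matrix)
    ref = sheet.reference_arrays()
    if not ref:
        raise ValueError("sample sheet declares no reference (parental) array")
    return matrix.values[ref].mean(axis=1)


def _default_floor(matrix_or_values: ExpressionMatrix | pd.Series | pd.DataFrame) -> float:
    if isinstance(matrix_or_values, ExpressionMatrix):
        arr = matrix_or_values.values.to_numpy()
    else:
        arr = np.asarray(matrix_or_values, dtype=float)
    positive = arr[arr > 0]
    if positive.size == 0:
        return 1.0
    return float(positive.min())


def fold_changes(
    values: pd.Series,
    profile: pd.Series,
    floor: float | None = None,
) -> pd.Series:
    """Per-probe fold change of one array column over the reference profile.

    ``FC(probe) = value / max(profile(probe), floor)``; the floor (default:
    the smallest positive reference value) keeps every ratio finite.
    """
    if floor is None:
        floor = _default_floor(profile)
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    profile = profile.reindex(values.index)
    denom = np.maximum(profile.to_numpy(dtype=float), floor)
    return pd.Series(values.to_numpy(dtype=float) / denom, index=values.index)


def build_gene_set(
    values: pd.Series,
    profile: pd.Series,
    array_id: str,
    threshold: float = 2.0,
    mode: Mode = "up",
    floor: float | None = None,
) -> GeneSet:
    """Apply the fold-change rule to one array column.

    Up-only mode selects probes with ``FC > threshold`` (strict); two-sided
    mode additionally selects ``FC < 1/threshold``.
    """
    if threshold <= 1:
        raise ValueError(f"threshold must exceed 1, got {threshold}")
    if mode not in ("up", "two-sided"):
        raise ValueError(f"unknown mode {mode!r}")
    fc = fold_changes(values, profile, floor=floor)
    selected = fc > threshold
    if mode == "two-sided":
        selected |= fc < 1.0 / threshold
    members = frozenset(fc.index[selected])
    return GeneSet(array_id=array_id, members=members, threshold=threshold, mode=mode)


def build_gene_sets(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    threshold: float = 2.0,
    mode: Mode = "up",
    floor: float | None = None,
    per_line: bool = False,
    include_reference: bool = False,
) -> list[GeneSet]:
    """Gene sets for every non-reference array (or cell line).

    The clustering leaves are individual arrays by default, one set per
    array; ``per_line=True`` instead builds one set per cell line from the
    line's mean intensity profile. Reference (parental) arrays are excluded
    unless ``include_reference`` is set.
    """
    sheet.validate_against(matrix)
    profile = reference_profile(matrix, sheet)
    if floor is None:
        floor = _default_floor(profile)
    sets: list[GeneSet] = []
    if per_line:
        for line in sheet.cell_lines:
            is_ref, _, _ = sheet.line_flags(line)
            if is_ref and not include_reference:
                continue
            arrays = [a for a in sheet.arrays_for_line(line) if a in matrix.values.columns]
            mean_col = matrix.values[arrays].mean(axis=1)
            sets.append(
                build_gene_set(mean_col, profile, line, threshold, mode, floor)
            )
    else:
        for rec in sheet.records:
            if rec.is_reference and not include_reference:
                continue
            if rec.array_id not in matrix.values.columns:
                continue
            sets.append(
                build_gene_set(
                    matrix.array(rec.array_id), profile, rec.array_id, threshold, mode, floor
                )
            )
    return sets


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_gene_sets_tsv(sets: Sequence[GeneSet], path) -> None:
    """Two-column TSV: array_id, probe_id (one row per member, sorted)."""
    rows = []
    for gs in sets:
        for probe in sorted(gs.members):
            rows.append((gs.array_id, probe))
    frame = pd.DataFrame(rows, columns=["array_id", "probe_id"])
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gene_sets_tsv(path, threshold: float = 2.0, mode: Mode = "up") -> list[GeneSet]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    sets = []
    for array_id, grp in frame.groupby("array_id", sort=False):
        sets.append(
            GeneSet(array_id=str(array_id), members=frozenset(grp["probe_id"]),
                    threshold=threshold, mode=mode)
        )
    return sets


def write_gene_sets_gmt(sets: Sequence[GeneSet], path) -> None:
    """GMT-style lines: set name, description, then members."""
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            desc = f"fold>{gs.threshold:g},{gs.mode}"
            fields = [gs.array_id, desc, *sorted(gs.members)]
            fh.write("\t".join(fields) + "\n")
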