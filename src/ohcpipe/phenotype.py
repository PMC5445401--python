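"""Dome-formation and transepithelial-resistance (TER) quantification.

Dome counts come as 21 per-field counts (100x fields) per T-25 flask; the
summary reports the mean number of domes per field, the mean per 21 fields
(exactly 21x the per-field mean) and a dome-positive flag (any dome seen).

TER records carry 8 raw resistance readings per filter (two sets of four at
two locations), a bare-filter blank and the membrane area; the filter value
is (mean reading - blank) x area. Daily summaries are mean +/- SEM over the
triplicate filters, and the combined day-5/6/7 value is the arithmetic mean
of the three daily means, reported to two decimals (round half to even).
The combined value is conventionally in Ohm*cm^2.

The dome phenotype is associated with gene-set expression by an exact
rank-sum permutation test over cell-line labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DomeRecord",
    "TerRecord",
    "DomeSummary",
    "dome_summary",
    "ter_filter_value",
    "ter_summary",
    "combined_daily_mean",
    "dome_geneset_association",
    "AssociationResult",
]

N_FIELDS = 21  # fields of view scored per T-25 flask
N_READINGS = 8  # two sets of four readings per filter


@dataclass(frozen=True)
class DomeRecord:
    """Per-flask dome counts: exactly 21 per-field counts."""

    flask_id: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if len(counts) != N_FIELDS:
            raise ValueError(
                f"flask {self.flask_id!r}: expected {N_FIELDS} field counts, "
                f"got {len(counts)}"
            )
        if any(c < 0 for c in counts):
            raise ValueError(f"flask {self.flask_id!r}: negative dome count")
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class TerRecord:
    """One filter on one day: 8 raw resistances, blank and membrane area."""

    filter_id: str
    day: int
    readings_ohm: tuple[float, ...]
    blank_ohm: float
    area_cm2: float

    def __post_init__(self) -> None:
        readings = tuple(float(r) for r in self.readings_ohm)
        if len(readings) != N_READINGS:
            raise ValueError(
                f"filter {self.filter_id!r} day {self.day}: expected "
                f"{N_READINGS} readings, got {len(readings)}"
            )
        if any(r <= 0 for r in readings):
            raise ValueError(f"filter {self.filter_id!r}: non-positive reading")
        if self.area_cm2 <= 0:
            raise ValueError(f"filter {self.filter_id!r}: non-positive area")
        object.__setattr__(self, "readings_ohm", readings)


@dataclass(frozen=True)
class DomeSummary:
    mean_per_field: float
    mean_per_21_fields: float
    dome_positive: bool


def dome_summary(records: Sequence[DomeRecord]) -> DomeSummary:
    """Mean domes per field / per 21 fields and a dome-positive flag."""
    if not records:
        raise ValueError("no dome records")
    total = sum(sum(r.counts) for r in records)
    per_field = total / (N_FIELDS * len(records))
    return DomeSummary(
        mean_per_field=per_field,
        mean_per_21_fields=per_field * N_FIELDS,
        dome_positive=total > 0,
    )


def ter_filter_value(record: TerRecord) -> float:
    """Blank-subtracted, area-scaled resistance of one filter (Ohm*cm^2)."""
    return (float(np.mean(record.readings_ohm)) - record.blank_ohm) * record.area_cm2


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def combined_daily_mean(daily_means: Sequence[float]) -> float:
    """Arithmetic mean of the daily TER means, to two decimals (half-even)."""
    if len(daily_means) == 0:
        raise ValueError("no daily means")
    return _round2(float(np.mean(daily_means)))


def ter_summary(records: Sequence[TerRecord], days: Sequence[int] = (5, 6, 7)) -> pd.DataFrame:
    """Per-day mean +/- SEM over filters, plus the combined-day mean.

    Returns a table with one row per day (columns: day, mean, sem, n) and
    attaches the combined value (two decimals) as
    ``DataFrame.attrs["combined"]``.
    """
    if not records:
        raise ValueError("no TER records")
    per_day: dict[int, list[float]] = {}
    for rec in records:
        per_day.setdefault(rec.day, []).append(ter_filter_value(rec))
    missing = [d for d in days if d not in per_day]
    if missing:
        raise ValueError(f"missing TER measurements for days {missing}")
    rows = []
    for d in days:
        vals = np.asarray(per_day[d], dtype=float)
        sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
        rows.append({"day": d, "mean": vals.mean(), "sem": sem, "n": vals.size})
    table = pd.DataFrame(rows)
    table.attrs["combined"] = combined_daily_mean(table["mean"].to_list())
    return table


@dataclass(frozen=True)
class AssociationResult:
    """Rank-sum permutation association of a phenotype with expression."""

    statistic: float  # rank sum of the phenotype-positive class
    p_value: float
    n_permutations: int
    exhaustive: bool


def dome_geneset_association(
    dome_positive: Mapping[str, bool],
    set_expression: Mapping[str, float],
    n_perm: int = 100_000,
    seed: int | None = None,
) -> AssociationResult:
    """Exact rank-sum test of set-level expression against the dome flag.

    The statistic is the sum of expression ranks of the dome-positive
    lines; the one-sided p-value (positive lines expressing higher) is the
    plain-count fraction of label assignments with a rank sum at least the
    observed one. All C(n, n_pos) assignments are enumerated when feasible
    (p >= 1/C(n, n_pos)); otherwise assignments are sampled with the
    add-one convention (seed required).
    """
    lines = list(dome_positive)
    if set(lines) != set(set_expression):
        raise ValueError("dome flags and expression must cover the same lines")
    flags = np.array([bool(dome_positive[l]) for l in lines])
    n_pos = int(flags.sum())
    n = len(lines)
    if n_pos == 0 or n_pos == n:
        raise ValueError("need at least one line in each phenotype class")
    expr = np.array([float(set_expression[l]) for l in lines])
    ranks = pd.Series(expr).rank(method="average").to_numpy()
    observed = float(ranks[flags].sum())

    n_distinct = comb(n, n_pos)
    if n_distinct <= n_perm:
        count = 0
        for combo in combinations(range(n), n_pos):
            if ranks[list(combo)].sum() >= observed - 1e-9:
                count += 1
        return AssociationResult(observed, count / n_distinct, n_distinct, True)
    if seed is None:
        raise ValueError("seed is required in sampled permutation mode")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.choice(n, size=n_pos, replace=False)
        if ranks[idx].sum() >= observed - 1e-9:
            count += 1
    return AssociationResult(observed, (1 + count) / (1 + n_perm), n_perm, False)
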