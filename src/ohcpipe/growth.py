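"""Doubling-time estimation from MTT growth curves.

The MTT absorbance at 570 nm is taken as proportional to viable cell
number, so during exponential growth log2(absorbance) is linear in time
with slope 1/T_d doublings per hour. The "linear region of the exponential
portion" is operationalised as the contiguous window (of at least
``min_window`` points) maximising the R-squared of the least-squares fit of
log2(blank-corrected absorbance) against time, subject to a positive slope;
ties go to the longer, then the earlier, window. The doubling time is the
reciprocal slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GrowthCurve",
    "DoublingTimeEstimate",
    "blank_correct",
    "doubling_time",
    "compare_doubling_times",
    "GrowthCurveModel",
    "DoublingTimeResults",
]

_FLOOR = 1e-6


@dataclass(frozen=True)
class GrowthCurve:
    """Absorbance-versus-time curve (time in hours, A570 per well)."""

    time_h: np.ndarray
    absorbance: np.ndarray  # shape (n_times,) or (n_times, n_wells)
    blank: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if t.ndim != 1 or t.size < 3:
            raise ValueError("need at least 3 strictly increasing time points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time points must be strictly increasing")
        if a.shape[0] != t.size:
            raise ValueError("absorbance rows must match time points")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance must be finite")
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "absorbance", a)

    def mean_absorbance(self) -> np.ndarray:
        a = self.absorbance
        return a if a.ndim == 1 else a.mean(axis=1)


@dataclass(frozen=True)
class DoublingTimeEstimate:
    """Doubling time in hours with fit window and goodness of fit."""

    td_hours: float
    slope: float  # log2 units per hour (doublings/h)
    r_squared: float
    window: tuple[int, int]  # start index, end index (inclusive)
    se_td: float  # delta-method standard error of T_d


def blank_correct(curve: GrowthCurve, blank: float | None = None,
                  floor: float = _FLOOR) -> GrowthCurve:
    """Subtract the blank absorbance, flooring at a small positive value.

    Values at or below the blank are floored (with a warning) so the log
    transform stays defined.
    """
    if blank is None:
        blank = curve.blank
    if not np.isfinite(blank):
        raise ValueError("blank must be finite")
    corrected = np.asarray(curve.absorbance, dtype=float) - blank
    if np.any(corrected <= 0) and blank != 0:
        warnings.warn("absorbance at or below blank; flooring before log transform")
    corrected = np.maximum(corrected, floor)
    return GrowthCurve(curve.time_h, corrected, blank=0.0)


def _fit_window(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, R^2 and slope SE of y ~ t."""
    res = stats.linregress(t, y)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return res.slope, 0.0, np.nan
    return float(res.slope), float(res.rvalue**2), float(res.stderr)


def doubling_time(curve: GrowthCurve, min_window: int = 3) -> DoublingTimeEstimate:
    """Estimate the doubling time from the best log-linear window.

    Scans all contiguous windows of at least ``min_window`` time points,
    fits log2(absorbance) against time, and keeps the positive-slope window
    with the highest R-squared (ties: longer, then earlier). Raises when no
    window has a positive slope ("no exponential region").
    """
    if min_window < 2:
        raise ValueError("min_window must be at least 2")
    corrected = blank_correct(curve)
    t = corrected.time_h
    y = np.log2(corrected.mean_absorbance())
    n = t.size
    if n < min_window:
        raise ValueError(f"need at least {min_window} time points, got {n}")
    best = None  # (r2, length, -start, slope, se, window)
    for start in range(0, n - min_window + 1):
        for stop in range(start + min_window, n + 1):
            slope, r2, se = _fit_window(t[start:stop], y[start:stop])
            if slope <= 0:
                continue
            key = (round(r2, 12), stop - start, -start)
            if best is None or key > best[0]:
                best = (key, slope, r2, se, (start, stop - 1))
    if best is None:
        raise ValueError("no exponential region: no window with positive slope")
    _, slope, r2, se_slope, window = best
    td = 1.0 / slope
    se_td = se_slope / slope**2 if np.isfinite(se_slope) else np.nan
    return DoublingTimeEstimate(
        td_hours=float(td), slope=float(slope), r_squared=float(r2),
        window=window, se_td=float(se_td),
    )


def compare_doubling_times(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """One-way ANOVA plus Tukey HSD over per-line doubling-time estimates.

    ``groups`` maps line name -> list of T_d estimates (>= 2 groups with
    >= 2 estimates each). Returns the Tukey pairwise table; the ANOVA F and
    p are attached as ``DataFrame.attrs["anova_f"]`` / ``["anova_p"]``.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs at least two estimates")
    f, p = stats.f_oneway(*samples)
    values = np.concatenate(samples)
    labels = np.concatenate([[g] * len(groups[g]) for g in names])
    tukey = pairwise_tukeyhsd(values, labels)
    table = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    table.attrs["anova_f"] = float(f)
    table.attrs["anova_p"] = float(p)
    return table


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class GrowthCurveModel:
    """Log-linear exponential-region model for one MTT growth curve."""

    def __init__(self, curve: GrowthCurve, min_window: int = 3):
        self.curve = curve
        self.min_window = min_window

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, blank: float = 0.0,
                       min_window: int = 3) -> "GrowthCurveModel":
        """Build from a long table with columns time_h, well, absorbance."""
        wide = frame.pivot_table(index="time_h", columns="well", values="absorbance")
        curve = GrowthCurve(wide.index.to_numpy(float), wide.to_numpy(float), blank=blank)
        return cls(curve, min_window=min_window)

    def fit(self) -> "DoublingTimeResults":
        est = doubling_time(self.curve, min_window=self.min_window)
        return DoublingTimeResults(self, est)


class DoublingTimeResults:
    def __init__(self, model: GrowthCurveModel, estimate: DoublingTimeEstimate):
        self.model = model
        self.estimate_ = estimate

    @property
    def td_hours(self) -> float:
        return self.estimate_.td_hours

    def summary(self) -> pd.Series:
        e = self.estimate_
        return pd.Series(
            {
                "td_hours": e.td_hours,
                "slope_log2_per_h": e.slope,
                "r_squared": e.r_squared,
                "window_start": e.window[0],
                "window_end": e.window[1],
                "se_td_hours": e.se_td,
            }
        )
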