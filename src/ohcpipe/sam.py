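"""SAM-style permutation differential expression.

A faithful re-implementation of the two-class unpaired Significance
Analysis of Microarrays statistic: the relative difference
``d_i = (xbar_A - xbar_B) / (s_i + s0)`` with ``s_i`` the two-sample pooled
standard error and ``s0`` a fudge factor chosen from percentiles of the
``s_i`` distribution to minimise the coefficient of variation of ``d``
across the range of ``s``. Significance comes from permutation of the
group labels: exhaustive enumeration of the distinct label assignments
when feasible (plain counting, which includes the observed assignment),
else seeded sampling with the add-one convention. P-values are adjusted
with the Benjamini-Hochberg step-up.

This is a re-implementation of the cited method, not a wrapper; the
original delta-threshold / median-false-positive machinery is out of scope.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleSheet

__all__ = [
    "pooled_se",
    "sam_statistic",
    "estimate_s0",
    "permutation_pvalues",
    "bh_fdr",
    "SamDE",
    "SamResults",
]

_S0_FLOOR = 1e-8


def _group_masks(labels: Sequence, n_min: int = 2) -> tuple[np.ndarray, np.ndarray, object, object]:
    labels = np.asarray(labels)
    uniq = list(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly two groups, got {uniq}")
    ga, gb = uniq
    mask_a = labels == ga
    mask_b = labels == gb
    if mask_a.sum() < n_min or mask_b.sum() < n_min:
        raise ValueError(
            f"each group needs at least {n_min} arrays "
            f"(got {int(mask_a.sum())} vs {int(mask_b.sum())})"
        )
    return mask_a, mask_b, ga, gb


def _mean_diff_and_se(values: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray):
    a = values[:, mask_a]
    b = values[:, mask_b]
    na, nb = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / na + 1.0 / nb) * ss / (na + nb - 2))
    return diff, s


def pooled_se(values: np.ndarray, labels: Sequence) -> np.ndarray:
    """Per-probe two-sample pooled standard error ``s_i``."""
    values = np.asarray(values, dtype=float)
    mask_a, mask_b, _, _ = _group_masks(labels)
    _, s = _mean_diff_and_se(values, mask_a, mask_b)
    return s


def sam_statistic(values: np.ndarray, labels: Sequence, s0: float) -> np.ndarray:
    """Per-probe relative difference ``d_i = (xbar_A - xbar_B)/(s_i + s0)``.

    Group A is the first label in order of appearance. ``s0 >= 0``.
    """
    if s0 < 0:
        raise ValueError(f"s0 must be non-negative, got {s0}")
    values = np.asarray(values, dtype=float)
    mask_a, mask_b, _, _ = _group_masks(labels)
    diff, s = _mean_diff_and_se(values, mask_a, mask_b)
    denom = s + s0
    if s0 == 0 and np.any(denom == 0):
        warnings.warn("zero pooled SE with s0=0; affected d_i are +/-inf or nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        return diff / denom


def estimate_s0(values: np.ndarray, labels: Sequence) -> float:
    """Tusher-style fudge-factor search.

    Candidates are the 0, 5, ..., 100 percentiles of the ``s_i``
    distribution. For each candidate, probes are binned into (up to) 100
    equal-occupancy bins of ``s_i``; within each bin the median absolute
    deviation of ``d_i`` (scaled by 1/0.64) is computed, and the candidate
    minimising the coefficient of variation of these scaled MADs across
    bins is returned. Deterministic given the input.
    """
    values = np.asarray(values, dtype=float)
    mask_a, mask_b, _, _ = _group_masks(labels)
    diff, s = _mean_diff_and_se(values, mask_a, mask_b)
    if np.all(s == 0):
        warnings.warn("all pooled SEs are zero; returning floor s0")
        return _S0_FLOOR
    if np.ptp(s) == 0:
        # all s_i equal: every percentile gives the same candidate
        return float(s[0])
    percentiles = np.arange(0, 101, 5)
    candidates = np.percentile(s, percentiles)
    order = np.argsort(s, kind="mergesort")
    n = s.size
    n_bins = min(100, n)
    # equal-occupancy bins over the sorted s values
    bin_edges = np.linspace(0, n, n_bins + 1).astype(int)
    best_cv = np.inf
    best_s0 = float(candidates[0])
    for s0 in candidates:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = diff / (s + s0)
        d_sorted = d[order]
        mads = []
        for b in range(n_bins):
            lo, hi = bin_edges[b], bin_edges[b + 1]
            if hi <= lo:
                continue
            seg = d_sorted[lo:hi]
            seg = seg[np.isfinite(seg)]
            if seg.size == 0:
                continue
            mads.append(np.median(np.abs(seg - np.median(seg))) / 0.64)
        mads = np.asarray(mads)
        if mads.size == 0 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean() if mads.size > 1 else 0.0
        if cv < best_cv - 1e-15:
            best_cv = cv
            best_s0 = float(s0)
    return max(best_s0, 0.0)


def _distinct_assignments(n: int, n_a: int) -> list[np.ndarray]:
    masks = []
    for combo in combinations(range(n), n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        masks.append(mask)
    return masks


def permutation_pvalues(
    values: np.ndarray,
    labels: Sequence,
    n_perm: int = 1000,
    seed: int | None = None,
    s0: float | None = None,
) -> tuple[np.ndarray, dict]:
    """Per-probe two-sided permutation p-values for the SAM statistic.

    When the number of distinct label assignments C(n, n_A) is at most
    ``n_perm``, all assignments are enumerated and p is the plain count
    ``#{|d*| >= |d|} / n_assignments`` (the observed assignment is one of
    them, so p >= 1/n_assignments). Otherwise ``n_perm`` random label
    shuffles are drawn (seed required) and the add-one convention
    ``p = (1 + count) / (1 + n_perm)`` is used. ``s0`` is estimated from
    the observed grouping when not supplied and is held fixed across
    permutations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = np.asarray(values, dtype=float)
    mask_a, mask_b, _, _ = _group_masks(labels)
    n = values.shape[1]
    n_a = int(mask_a.sum())
    if s0 is None:
        s0 = estimate_s0(values, labels)
    d_obs = sam_statistic(values, labels, s0)
    abs_obs = np.abs(d_obs)

    from math import comb

    n_distinct = comb(n, n_a)
    exhaustive = n_distinct <= n_perm
    count = np.zeros(values.shape[0])
    if exhaustive:
        for mask in _distinct_assignments(n, n_a):
            diff, s = _mean_diff_and_se(values, mask, ~mask)
            with np.errstate(divide="ignore", invalid="ignore"):
                d_star = diff / (s + s0)
            count += np.abs(d_star) >= abs_obs - 1e-12
        p = count / n_distinct
        meta = {"mode": "exhaustive", "n_perm": n_distinct, "s0": float(s0), "seed": seed}
    else:
        if seed is None:
            raise ValueError("seed is required in sampled permutation mode")
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            mask = np.zeros(n, dtype=bool)
            mask[perm[:n_a]] = True
            diff, s = _mean_diff_and_se(values, mask, ~mask)
            with np.errstate(divide="ignore", invalid="ignore"):
                d_star = diff / (s + s0)
            count += np.abs(d_star) >= abs_obs - 1e-12
        p = (1.0 + count) / (1.0 + n_perm)
        meta = {"mode": "sampled", "n_perm": n_perm, "s0": float(s0), "seed": seed}
    return p, meta


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class SamDE:
    """Two-class unpaired SAM differential-expression model.

    Parameters
    ----------
    values
        probes x arrays intensity array (or DataFrame).
    labels
        Per-array group labels; exactly two distinct values, the first in
        order of appearance is group A (mean difference is A - B).
    probe_ids
        Optional probe identifiers (taken from the DataFrame index when
        ``values`` is a DataFrame).
    """

    def __init__(self, values, labels: Sequence, probe_ids: Sequence[str] | None = None):
        if isinstance(values, pd.DataFrame):
            if probe_ids is None:
                probe_ids = list(values.index)
            values = values.to_numpy()
        self.values = np.asarray(values, dtype=float)
        self.labels = np.asarray(labels)
        if self.values.shape[1] != self.labels.size:
            raise ValueError("labels length must match number of arrays")
        self.probe_ids = (
            list(probe_ids) if probe_ids is not None
            else [f"probe{i}" for i in range(self.values.shape[0])]
        )
        _group_masks(self.labels)

    @classmethod
    def from_matrix(
        cls,
        matrix: ExpressionMatrix,
        sheet: SampleSheet,
        line_a: str,
        line_b: str,
    ) -> "SamDE":
        """Compare two cell lines from a matrix plus sample sheet."""
        arrays_a = sheet.arrays_for_line(line_a)
        arrays_b = sheet.arrays_for_line(line_b)
        if not arrays_a or not arrays_b:
            raise ValueError(f"no arrays found for {line_a!r} or {line_b!r}")
        sub = matrix.values[arrays_a + arrays_b]
        labels = [line_a] * len(arrays_a) + [line_b] * len(arrays_b)
        return cls(sub, labels)

    def fit(
        self, n_perm: int = 1000, seed: int | None = None, s0: float | None = None
    ) -> "SamResults":
        if s0 is None:
            s0 = estimate_s0(self.values, self.labels)
        mask_a, mask_b, ga, gb = _group_masks(self.labels)
        diff, s = _mean_diff_and_se(self.values, mask_a, mask_b)
        d = sam_statistic(self.values, self.labels, s0)
        p, meta = permutation_pvalues(self.values, self.labels, n_perm, seed, s0)
        q = bh_fdr(p)
        return SamResults(self, diff, s, d, p, q, float(s0), meta, (ga, gb))


class SamResults:
    """Fitted SAM results: per-probe statistics and multiplicity-adjusted q."""

    def __init__(self, model, mean_diff, s, d, p, q, s0, perm_meta, groups):
        self.model = model
        self.mean_diff_ = mean_diff
        self.s_ = s
        self.d_ = d
        self.p_ = p
        self.q_ = q
        self.s0_ = s0
        self.perm_meta_ = perm_meta
        self.groups_ = groups

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.model.probe_ids,
                "mean_diff": self.mean_diff_,
                "s": self.s_,
                "d": self.d_,
                "p": self.p_,
                "q": self.q_,
            }
        )

    def significant(self, q_max: float = 0.05) -> pd.DataFrame:
        tbl = self.summary()
        return tbl[tbl["q"] < q_max].sort_values("q", kind="mergesort")

    def to_tsv(self, path, sidecar_path=None) -> None:
        """Write the results table; run metadata goes to a JSON sidecar."""
        self.summary().to_csv(path, sep="\t", index=False, lineterminator="\n")
        if sidecar_path is not None:
            meta = {
                "s0": self.s0_,
                "groups": [str(g) for g in self.groups_],
                **{k: v for k, v in self.perm_meta_.items()},
            }
            with open(sidecar_path, "w", encoding="utf-8") as fh:
                json.dump(meta, fh, indent=2, sort_keys=True)
                fh.write("\n")
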