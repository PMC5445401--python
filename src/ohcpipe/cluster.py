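"""Overlap hierarchical clustering (OHC).

Arrays are compared through the overlap (Jaccard) distance between their
fold-change gene sets, D(A, B) = 1 - |A n B| / |A u B|, and agglomerated
with Ward's linkage applied to the precomputed distances via the
Lance-Williams recurrence. The default variant applies the recurrence to
squared distances and reports square-root merge heights (the convention of
scipy's and R's ``ward.D2``); the unsquared variant is selectable.

Ward's coefficients satisfy the reducibility condition, so merge heights
are non-decreasing for either variant; an inversion check is kept and
logged for safety.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .genesets import GeneSet
from .io import DistanceMatrix

__all__ = [
    "overlap_distance",
    "distance_matrix",
    "ward_agglomerate",
    "cut_tree",
    "to_newick",
    "OverlapClustering",
    "OverlapClusteringResults",
]

logger = logging.getLogger(__name__)

WardVariant = Literal["squared", "unsquared"]


def overlap_distance(a: GeneSet | frozenset | set, b: GeneSet | frozenset | set) -> float:
    """Jaccard distance between two gene sets: 1 - |A n B| / |A u B|.

    Two empty sets are identical objects and get distance 0 (logged);
    exactly one empty set gives distance 1.
    """
    sa = a.members if isinstance(a, GeneSet) else frozenset(a)
    sb = b.members if isinstance(b, GeneSet) else frozenset(b)
    union = len(sa | sb)
    if union == 0:
        logger.warning("overlap_distance of two empty sets: returning 0 by convention")
        return 0.0
    return 1.0 - len(sa & sb) / union


def distance_matrix(sets: Sequence[GeneSet]) -> DistanceMatrix:
    """Pairwise overlap distances between gene sets, one label per array."""
    if len(sets) < 2:
        raise ValueError("need at least two gene sets")
    labels = [gs.array_id for gs in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate array ids among gene sets")
    n = len(sets)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = overlap_distance(sets[i], sets[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


def ward_agglomerate(dm: DistanceMatrix, variant: WardVariant = "squared") -> np.ndarray:
    """Agglomerate a precomputed distance matrix with Ward's linkage.

    Implements the Lance-Williams recurrence
    ``d(k, i+j) = ((n_i+n_k) d(k,i) + (n_j+n_k) d(k,j) - n_k d(i,j)) / (n_i+n_j+n_k)``
    on squared distances (default; heights reported as square roots) or on
    the raw distances. Ties in the minimum inter-cluster distance are broken
    toward the lowest (i, j) cluster-id pair. Returns a linkage matrix in
    scipy's convention: rows of (id_i, id_j, height, size), new clusters
    numbered n, n+1, ...
    """
    if variant not in ("squared", "unsquared"):
        raise ValueError(f"unknown Ward variant {variant!r}")
    n = dm.n
    if n < 2:
        raise ValueError("need at least two observations")
    work = dm.values.astype(float).copy()
    if variant == "squared":
        work = work**2
    np.fill_diagonal(work, np.inf)

    # cluster bookkeeping: row/col slots hold current clusters
    ids = list(range(n))
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))  # indices into `work`
    slot_id = {i: i for i in range(n)}  # work-slot -> cluster id
    Z = np.zeros((n - 1, 4))
    prev_height = -np.inf
    for step in range(n - 1):
        # minimum over active pairs, ties to lowest (id_i, id_j)
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                si, sj = active[ai], active[aj]
                w = work[si, sj]
                ci, cj = sorted((slot_id[si], slot_id[sj]))
                key = (w, ci, cj)
                if best is None or key < best[0]:
                    best = (key, si, sj)
        (w, ci, cj), si, sj = best
        height = float(np.sqrt(w)) if variant == "squared" else float(w)
        if height < prev_height - 1e-12:
            logger.warning(
                "height inversion at merge %d: %.6g < %.6g", step, height, prev_height
            )
        prev_height = max(prev_height, height)
        new_id = n + step
        ni, nj = sizes[slot_id[si]], sizes[slot_id[sj]]
        Z[step] = (ci, cj, height, ni + nj)
        # Lance-Williams update into slot si; retire slot sj
        for sk in active:
            if sk in (si, sj):
                continue
            nk = sizes[slot_id[sk]]
            upd = ((ni + nk) * work[sk, si] + (nj + nk) * work[sk, sj] - nk * w) / (
                ni + nj + nk
            )
            work[sk, si] = work[si, sk] = upd
        work[sj, :] = np.inf
        work[:, sj] = np.inf
        sizes[new_id] = ni + nj
        slot_id[si] = new_id
        active.remove(sj)
    return Z


def cut_tree(Z: np.ndarray, k: int, labels: Sequence[str] | None = None) -> pd.Series:
    """Cut the merge tree into ``k`` clusters from the top.

    Returns integer cluster labels per leaf (in leaf order, or indexed by
    ``labels`` when given). Label assignment is deterministic: clusters are
    numbered by first leaf appearance.
    """
    n = Z.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = sch.cut_tree(Z, n_clusters=k).ravel()
    # renumber deterministically by first appearance
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, c in enumerate(raw):
        if c not in mapping:
            mapping[c] = len(mapping)
        out[i] = mapping[c]
    index = list(labels) if labels is not None else list(range(n))
    return pd.Series(out, index=index, name="cluster")


def _newick_escape(label: str) -> str:
    if any(c in label for c in " ():,;'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(Z: np.ndarray, leaf_labels: Sequence[str]) -> str:
    """Render the merge tree as a Newick string with branch lengths.

    Midpoint convention: a node sits at depth ``height/2``, so a child's
    branch length is ``(parent_height - child_height) / 2`` and leaves sit
    at depth 0. Two leaves merged at height 0.4 give ``(a:0.2,b:0.2);``.
    """
    n = Z.shape[0] + 1
    if len(leaf_labels) != n:
        raise ValueError(f"expected {n} leaf labels, got {len(leaf_labels)}")
    heights = {i: 0.0 for i in range(n)}
    newick = {i: _newick_escape(str(lab)) for i, lab in enumerate(leaf_labels)}
    for step in range(n - 1):
        i, j, h, _ = Z[step]
        i, j = int(i), int(j)
        node = n + step
        heights[node] = float(h)
        bi = (heights[node] - heights[i]) / 2.0
        bj = (heights[node] - heights[j]) / 2.0
        newick[node] = f"({newick[i]}:{bi:.10g},{newick[j]}:{bj:.10g})"
    return newick[2 * n - 2] + ";"


def linkage_table(Z: np.ndarray) -> pd.DataFrame:
    """Merge list as a DataFrame (cluster_i, cluster_j, height, size)."""
    return pd.DataFrame(
        {
            "cluster_i": Z[:, 0].astype(int),
            "cluster_j": Z[:, 1].astype(int),
            "height": Z[:, 2],
            "size": Z[:, 3].astype(int),
        }
    )


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class OverlapClustering:
    """Overlap hierarchical clustering model over per-array gene sets.

    Parameters
    ----------
    gene_sets
        Gene sets, one per array (clustering leaf). Alternatively build the
        model from a precomputed :class:`~ohcpipe.io.DistanceMatrix` with
        :meth:`from_distance_matrix`.
    variant
        Ward Lance-Williams variant: ``"squared"`` (default) or
        ``"unsquared"``.
    """

    def __init__(self, gene_sets: Sequence[GeneSet] | None, variant: WardVariant = "squared",
                 distance: DistanceMatrix | None = None):
        if (gene_sets is None) == (distance is None):
            raise ValueError("provide either gene_sets or a distance matrix")
        self.gene_sets = list(gene_sets) if gene_sets is not None else None
        self.variant = variant
        self._distance = distance

    @classmethod
    def from_distance_matrix(cls, dm: DistanceMatrix, variant: WardVariant = "squared"):
        return cls(None, variant=variant, distance=dm)

    def fit(self) -> "OverlapClusteringResults":
        dm = self._distance if self._distance is not None else distance_matrix(self.gene_sets)
        Z = ward_agglomerate(dm, variant=self.variant)
        return OverlapClusteringResults(self, dm, Z)


class OverlapClusteringResults:
    """Fitted OHC dendrogram: merge tree, heights and leaf labels."""

    def __init__(self, model: OverlapClustering, distance: DistanceMatrix, linkage: np.ndarray):
        self.model = model
        self.distance_ = distance
        self.linkage_ = linkage
        self.labels_ = list(distance.labels)

    @property
    def heights_(self) -> np.ndarray:
        return self.linkage_[:, 2]

    def cut(self, k: int) -> pd.Series:
        return cut_tree(self.linkage_, k, labels=self.labels_)

    def to_newick(self) -> str:
        return to_newick(self.linkage_, self.labels_)

    def linkage_table(self) -> pd.DataFrame:
        return linkage_table(self.linkage_)

    def summary(self) -> pd.DataFrame:
        tbl = self.linkage_table()
        tbl.insert(0, "merge", np.arange(1, len(tbl) + 1))
        return tbl

    def plot_dendrogram(self, ax=None, **kwargs):
        """Basic dendrogram plot via scipy/matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        sch.dendrogram(self.linkage_, labels=self.labels_, ax=ax, **kwargs)
        ax.set_ylabel("overlap distance (Ward height)")
        return ax
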