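"""Hierarchical clustering of target-gene expression across cell types.

This is the heatmap computation behind the screens: rows (genes) are
z-scored, and both rows and columns are clustered agglomeratively with
1 - Pearson correlation distance and average linkage by default. The
agglomeration is implemented here rather than delegated so that tie-breaking
is fully specified — when several cluster pairs are equidistant the pair with
the lexicographically smallest (cluster id, cluster id) label is merged —
which makes merge sequences reproducible and directly checkable against a
from-scratch recomputation.

Cluster ids follow the scipy convention: original rows are 0..n-1 and the
cluster created by merge step m gets id n + m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ProfilingError(ValueError):
    pass


@dataclass
class ClusterResult:
    merges: list[tuple[int, int, float, int]]   # (id_a, id_b, height, size)
    leaf_order: list[str]
    labels: list[str]
    linkage: str = "average"
    metric: str = "correlation"

    def to_newick(self) -> str:
        """Merge list rendered as a Newick-like nested string with heights."""
        n = len(self.labels)
        node: dict[int, str] = {i: self.labels[i] for i in range(n)}
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        for m, (a, b, h, _size) in enumerate(self.merges):
            la = f"{node[a]}:{h - height[a]:.6g}"
            lb = f"{node[b]}:{h - height[b]:.6g}"
            node[n + m] = f"({la},{lb})"
            height[n + m] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return node[root] + ";"

    def top_split(self) -> tuple[set[str], set[str]]:
        """Leaf labels under each child of the root merge."""
        if not self.merges:
            raise ProfilingError("no merges: fewer than 2 items clustered")
        n = len(self.labels)
        members: dict[int, set[str]] = {i: {self.labels[i]} for i in range(n)}
        for m, (a, b, _h, _size) in enumerate(self.merges):
            members[n + m] = members[a] | members[b]
        a, b, _, _ = self.merges[-1]
        return members[a], members[b]


def standardize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-row z-score (mean 0, sd 1). Zero-variance rows become all-zero.

    Returns the z-matrix and the list of flagged constant rows. Requires at
    least 2 columns, otherwise the sd is degenerate.
    """
    if matrix.shape[1] < 2:
        raise ProfilingError("standardization needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    flagged = list(matrix.index[(sd == 0).ravel()])
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / sd_safe
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns), flagged


def _pairwise_distance(values: np.ndarray, metric: str) -> np.ndarray:
    if metric == "correlation":
        # constant rows have undefined correlation; treated as distance 1
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(values)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        dist = 1.0 - corr
    elif metric == "euclidean":
        diff = values[:, None, :] - values[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2))
    else:
        raise ProfilingError(f"unknown metric {metric!r}")
    np.fill_diagonal(dist, 0.0)
    return np.maximum(dist, 0.0)


def hierarchical_cluster(matrix: pd.DataFrame, metric: str = "correlation",
                         linkage: str = "average",
                         precomputed: np.ndarray | None = None) -> ClusterResult:
    """Agglomerative clustering of the rows of ``matrix``.

    Distances update by the Lance-Williams recurrences (average: size-weighted
    mean of the merged members' distances; complete: max). Equidistant merge
    candidates resolve to the smallest (id, id) pair. Leaf order follows the
    tighter-cluster-first recursion: within each merge the child with the
    lower own merge height is emitted first, ids breaking ties.
    """
    labels = [str(i) for i in matrix.index]
    n = len(labels)
    if n < 2:
        raise ProfilingError("clustering needs at least 2 rows")
    if linkage not in ("average", "complete"):
        raise ProfilingError(f"unknown linkage {linkage!r}")

    dist = (np.asarray(precomputed, dtype=float).copy()
            if precomputed is not None
            else _pairwise_distance(matrix.to_numpy(dtype=float), metric))
    if dist.shape != (n, n):
        raise ProfilingError("distance matrix shape mismatch")

    active: dict[int, int] = {i: i for i in range(n)}     # cluster id -> slot
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    merges: list[tuple[int, int, float, int]] = []

    for step in range(n - 1):
        ids = sorted(active)
        best = None
        for ai, a in enumerate(ids):
            for b in ids[ai + 1:]:
                d = dist[active[a], active[b]]
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        new_id = n + step
        # Lance-Williams update written into a's slot; b's slot retired
        sa, sb = sizes[a], sizes[b]
        ia, ib = active[a], active[b]
        for c in ids:
            if c in (a, b):
                continue
            ic = active[c]
            if linkage == "average":
                nd = (sa * dist[ia, ic] + sb * dist[ib, ic]) / (sa + sb)
            else:
                nd = max(dist[ia, ic], dist[ib, ic])
            dist[ia, ic] = dist[ic, ia] = nd
        del active[a], active[b]
        active[new_id] = ia
        sizes[new_id] = sa + sb
        heights[new_id] = d
        children[new_id] = (a, b)
        merges.append((a, b, float(d), sa + sb))

    def emit(cid: int) -> list[str]:
        if cid < n:
            return [labels[cid]]
        a, b = children[cid]
        first, second = sorted((a, b), key=lambda c: (heights[c], c))
        return emit(first) + emit(second)

    leaf_order = emit(n + n - 2)
    return ClusterResult(merges=merges, leaf_order=leaf_order, labels=labels,
                         linkage=linkage, metric=metric)


def cluster_profile(matrix: pd.DataFrame, metric: str = "correlation",
                    linkage: str = "average") -> dict:
    """Row and column dendrograms plus the standardized matrix for rendering."""
    z, flagged = standardize(matrix)
    rows = hierarchical_cluster(z, metric=metric, linkage=linkage)
    cols = hierarchical_cluster(z.T, metric=metric, linkage=linkage)
    return {"z": z, "rows": rows, "columns": cols, "constant_rows": flagged}
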