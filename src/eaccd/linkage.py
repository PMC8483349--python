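"""Agglomerative clustering with minimax linkage.

At each step the pair of clusters whose union has the smallest *minimax
radius* is merged, where the radius of a candidate cluster G is
``min_{p in G} max_{x in G} d(p, x)`` and the minimising member p is the
cluster's *prototype*.  The merge height is the radius, so every internal
node of the dendrogram is a ball of that radius centred at an actual
combination — which is what makes the tree directly interpretable for
prognostic grouping.

Minimax linkage can produce height inversions; they are flagged in the
dendrogram metadata, and cutting is by merge order (undoing the last k-1
merges), so inversions never affect the groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dissimilarity import DissimilarityMatrix

__all__ = ["Merge", "Dendrogram", "minimax_linkage", "cut"]


@dataclass(frozen=True)
class Merge:
    """One agglomeration: cluster ids follow the scipy convention
    (leaves 0..M-1; the i-th merge creates cluster M+i)."""

    left: int
    right: int
    height: float
    prototype: int  # leaf index of the merged cluster's prototype
    members: tuple  # leaf indices of the merged cluster


@dataclass(frozen=True)
class Dendrogram:
    keys: tuple
    merges: tuple
    has_inversions: bool

    @property
    def m(self) -> int:
        return len(self.keys)

    def linkage_matrix(self) -> np.ndarray:
        """scipy-style (M-1, 4) linkage matrix for plotting.

        Heights are made monotone for display only (cumulative max); the
        raw heights live on the merges.
        """
        z = np.zeros((len(self.merges), 4))
        h = 0.0
        for i, mg in enumerate(self.merges):
            h = max(h, mg.height)
            z[i] = [mg.left, mg.right, h, len(mg.members)]
        return z

    def to_newick(self) -> str:
        """Newick string; internal node labels are prototype keys, branch
        lengths are parent height minus child height (floored at 0)."""
        m = self.m
        height = {i: 0.0 for i in range(m)}
        node = {i: self.keys[i] for i in range(m)}
        for i, mg in enumerate(self.merges):
            cid = m + i
            height[cid] = mg.height
            parts = []
            for child in (mg.left, mg.right):
                bl = max(mg.height - height[child], 0.0)
                parts.append(f"{node[child]}:{bl:.10g}")
            node[cid] = f"({parts[0]},{parts[1]}){self.keys[mg.prototype]}"
        root = m + len(self.merges) - 1 if self.merges else 0
        return node[root] + ";"

    def merges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(1, len(self.merges) + 1),
                "left": [mg.left for mg in self.merges],
                "right": [mg.right for mg in self.merges],
                "height": [mg.height for mg in self.merges],
                "prototype": [self.keys[mg.prototype] for mg in self.merges],
                "size": [len(mg.members) for mg in self.merges],
            }
        )


def _radius_and_prototype(dist: np.ndarray, members: np.ndarray):
    """Minimax radius and prototype (ties to the lowest leaf index)."""
    sub = dist[np.ix_(members, members)]
    worst = sub.max(axis=1)
    p = int(np.argmin(worst))  # first minimum: lowest index in sorted members
    return float(worst[p]), int(members[p])


def minimax_linkage(D: DissimilarityMatrix) -> Dendrogram:
    """Build the minimax-linkage dendrogram over a dissimilarity matrix.

    Deterministic: among equal-radius candidate merges the lexicographically
    smallest (cluster-id) pair wins; among equally eccentric prototype
    candidates the lowest leaf index wins.
    """
    dist = D.values
    if not np.array_equal(dist, dist.T) or np.any(dist < 0):
        raise ValueError("minimax_linkage requires a symmetric non-negative matrix")
    m = dist.shape[0]
    if m < 2:
        raise ValueError("need at least 2 items")

    # active clusters: id -> sorted array of leaf members
    active: dict[int, np.ndarray] = {i: np.array([i]) for i in range(m)}
    merges: list[Merge] = []
    radius_cache: dict[tuple, tuple] = {}

    for step in range(m - 1):
        best = None  # (radius, (id_a, id_b), prototype, members)
        ids = sorted(active)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                key = (a, b)
                if key not in radius_cache:
                    members = np.sort(np.concatenate((active[a], active[b])))
                    radius_cache[key] = (*_radius_and_prototype(dist, members), members)
                r, proto, members = radius_cache[key]
                if best is None or r < best[0]:
                    best = (r, (a, b), proto, members)
        r, (a, b), proto, members = best
        del active[a], active[b]
        radius_cache = {k: v for k, v in radius_cache.items() if a not in k and b not in k}
        new_id = m + step
        active[new_id] = members
        merges.append(Merge(left=a, right=b, height=r, prototype=proto, members=tuple(members)))

    heights = [mg.height for mg in merges]
    has_inv = any(h2 < h1 for h1, h2 in zip(heights, heights[1:]))
    return Dendrogram(keys=D.keys, merges=tuple(merges), has_inversions=has_inv)


def cut(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Labels of the k clusters obtained by undoing the last k-1 merges.

    Labels are 0..k-1 in order of first leaf appearance (the cluster
    containing the lowest-index leaf gets label 0, and so on).
    """
    m = dendrogram.m
    if not 1 <= k <= m:
        raise ValueError(f"k={k} out of range [1, {m}]")
    parent = list(range(m))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for mg in dendrogram.merges[: m - k]:
        for leaf in mg.members:
            parent[find(leaf)] = find(mg.members[0])

    roots = [find(i) for i in range(m)]
    labels = np.empty(m, dtype=int)
    seen: dict[int, int] = {}
    for i, r in enumerate(roots):
        if r not in seen:
            seen[r] = len(seen)
        labels[i] = seen[r]
    return labels
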