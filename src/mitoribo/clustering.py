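"""Replicate profile comparison by 1 - Pearson distance and hierarchical
clustering.

Replicate codon profiles (and the genomic abundance profile alongside
them) are compared pairwise by ``D_ij = 1 - r_ij`` with ``r`` the Pearson
correlation coefficient, then clustered agglomeratively.  The
agglomeration is written out here rather than delegated so that
tie-breaking is fully deterministic (smallest cluster index wins), which
the scipy implementation does not guarantee; tests cross-check the merge
heights against ``scipy.cluster.hierarchy.linkage`` on tie-free inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

LINKAGES = ("complete", "average", "single")


@dataclass
class DistanceMatrix:
    """Symmetric 1-Pearson distance matrix; entries in [0, 2], zero diagonal."""

    labels: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("distance matrix is not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)


def pearson_distance_matrix(
    profiles: Sequence, labels: Sequence[str] | None = None
) -> DistanceMatrix:
    """``D_ij = 1 - r(profile_i, profile_j)`` over 64-codon vectors.

    Accepts raw vectors or objects with a ``fractions`` attribute
    (:class:`~mitoribo.occupancy.FractionalCodonProfile`).  Pearson r is
    invariant to each profile's affine scale, so fractional and count
    profiles cluster identically.
    """
    vecs = []
    auto_labels = []
    for i, p in enumerate(profiles):
        if hasattr(p, "fractions"):
            vecs.append(np.asarray(p.fractions, dtype=float))
            auto_labels.append(getattr(p, "replicate_id", "") or f"profile{i}")
        else:
            vecs.append(np.asarray(p, dtype=float))
            auto_labels.append(f"profile{i}")
    if len(vecs) < 2:
        raise ValueError("need at least 2 profiles")
    if labels is None:
        labels = auto_labels
    labels = list(labels)
    X = np.stack(vecs, axis=0)
    sd = X.std(axis=1)
    for lab, s in zip(labels, sd):
        if s == 0:
            raise ValueError(f"profile {lab!r} has zero variance")
    R = np.corrcoef(X)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    return DistanceMatrix(labels=labels, D=D)


@dataclass
class Dendrogram:
    """Agglomeration result: n-1 merges over leaves 0..n-1.

    ``merges[k] = (a, b, height)`` joins clusters ``a`` and ``b`` (leaf ids
    or ``n + j`` for the cluster formed at earlier merge ``j``) into
    cluster ``n + k``.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def members(self, cluster: int) -> frozenset[int]:
        n = self.n_leaves
        if cluster < n:
            return frozenset([cluster])
        a, b, _ = self.merges[cluster - n]
        return self.members(a) | self.members(b)

    def top_split(self) -> tuple[frozenset[str], frozenset[str]]:
        """Leaf labels on the two sides of the final (root) merge."""
        a, b, _ = self.merges[-1]
        left = frozenset(self.labels[i] for i in self.members(a))
        right = frozenset(self.labels[i] for i in self.members(b))
        return left, right

    @property
    def leaf_order(self) -> list[int]:
        def walk(cluster: int) -> list[int]:
            n = self.n_leaves
            if cluster < n:
                return [cluster]
            a, b, _ = self.merges[cluster - n]
            return walk(a) + walk(b)

        return walk(self.n_leaves + len(self.merges) - 1)

    def to_newick(self) -> str:
        heights = {}
        n = self.n_leaves
        for k, (_, _, h) in enumerate(self.merges):
            heights[n + k] = h
        for i in range(n):
            heights[i] = 0.0

        def render(cluster: int, parent_height: float) -> str:
            branch = parent_height - heights[cluster]
            if cluster < n:
                return f"{self.labels[cluster]}:{branch:.6g}"
            a, b, h = self.merges[cluster - n]
            return f"({render(a, h)},{render(b, h)}):{branch:.6g}"

        root = n + len(self.merges) - 1
        _, _, root_h = self.merges[-1]
        a, b, _ = self.merges[-1]
        return f"({render(a, root_h)},{render(b, root_h)});"


def hierarchical_cluster(
    dm: DistanceMatrix, linkage: str = "complete"
) -> Dendrogram:
    """Agglomerative clustering under complete/average/single linkage.

    Average linkage is UPGMA (merge distance weighted by cluster sizes).
    Ties are broken deterministically towards the smallest cluster-index
    pair.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")

    # distances between active clusters, keyed by frozenset of cluster ids
    dist: dict[frozenset[int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = float(dm.D[i, j])
    active: dict[int, int] = {i: 1 for i in range(n)}  # id -> size
    merges: list[tuple[int, int, float]] = []

    for step in range(n - 1):
        best = None
        ids = sorted(active)
        for ai, a in enumerate(ids):
            for b in ids[ai + 1 :]:
                d = dist[frozenset((a, b))]
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        new = n + step
        for other in ids:
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            if linkage == "complete":
                dn = max(da, db)
            elif linkage == "single":
                dn = min(da, db)
            else:  # average (UPGMA)
                dn = (active[a] * da + active[b] * db) / (active[a] + active[b])
            dist[frozenset((new, other))] = dn
        dist.pop(frozenset((a, b)))
        active[new] = active.pop(a) + active.pop(b)
        merges.append((a, b, d))

    return Dendrogram(labels=list(dm.labels), merges=merges)
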