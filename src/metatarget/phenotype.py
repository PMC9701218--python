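"""Phenotype-based disease clustering.

Diseases are described by vectors of clinical-feature prevalences in [0, 1].
They are grouped by agglomerative hierarchical clustering with *uncentered
correlation* similarity (cosine similarity; Pearson without mean-centering)
and average linkage (UPGMA), the classic combination used by Cluster/TreeView
-style phenotype clustering tools.  The distance is ``d = 1 - similarity``,
so all dendrogram heights lie in [0, 2].

The agglomeration is implemented directly (the number of diseases is tens,
so the O(n^3) naive scheme is instantaneous) with a deterministic tie-break:
among equally distant pairs the one with the lexicographically smallest
(cluster_a, cluster_b) index pair merges first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UndefinedSimilarityError",
    "PhenotypePrevalenceMatrix",
    "Dendrogram",
    "uncentered_similarity",
    "hierarchical_cluster",
    "cut_clusters",
    "load_prevalence_tsv",
]


class UndefinedSimilarityError(ValueError):
    """Raised when a similarity is requested for a zero-norm vector."""


@dataclass
class PhenotypePrevalenceMatrix:
    """Diseases x clinical features matrix of prevalences in [0, 1]."""

    diseases: list[str]
    features: list[str]
    P: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (len(self.diseases), len(self.features)):
            raise ValueError(
                f"matrix shape {self.P.shape} does not match "
                f"{len(self.diseases)} diseases x {len(self.features)} features"
            )
        if np.isnan(self.P).any():
            raise ValueError(
                "missing prevalence values; impute before clustering "
                "(impute='feature_mean') or fix the input"
            )
        if (self.P < 0).any() or (self.P > 1).any():
            raise ValueError("prevalences must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.diseases, columns=self.features)


@dataclass
class Dendrogram:
    """Full merge tree from agglomerative clustering.

    ``merges`` lists (node_a, node_b, height, new_node) in merge order;
    leaves are numbered 0..n-1, internal nodes n..2n-2, mirroring the
    scipy linkage convention.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges, got {len(self.merges)}")
        heights = [h for _, _, h, _ in self.merges]
        if any(h < -1e-12 for h in heights):
            raise ValueError("negative merge height")
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def _members(self) -> dict[int, list[int]]:
        members = {i: [i] for i in range(self.n_leaves)}
        for a, b, _, new in self.merges:
            members[new] = members[a] + members[b]
        return members

    def cophenetic_matrix(self) -> np.ndarray:
        """Pairwise merge heights between leaves (the cophenetic distances)."""
        n = self.n_leaves
        members = {i: [i] for i in range(n)}
        C = np.zeros((n, n))
        for a, b, h, new in self.merges:
            for i in members[a]:
                for j in members[b]:
                    C[i, j] = C[j, i] = h
            members[new] = members[a] + members[b]
        return C

    def to_newick(self) -> str:
        """Serialize with heights as ultrametric branch lengths."""
        height = {i: 0.0 for i in range(self.n_leaves)}
        rep: dict[int, str] = {
            i: name.replace(" ", "_") for i, name in enumerate(self.leaves)
        }
        for a, b, h, new in self.merges:
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            rep[new] = f"({rep[a]}:{la:.6g},{rep[b]}:{lb:.6g})"
            height[new] = h
        root = self.merges[-1][3] if self.merges else 0
        return rep[root] + ";"


def uncentered_similarity(x, y) -> float:
    """Cosine similarity sum(x*y) / (||x|| * ||y||), in [-1, 1].

    This is the "uncentered correlation" of clustering tools: Pearson's r
    computed without subtracting the means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("inputs must be equal-length 1-d vectors")
    nx = float(np.sqrt(np.sum(x * x)))
    ny = float(np.sqrt(np.sum(y * y)))
    if nx == 0.0 or ny == 0.0:
        raise UndefinedSimilarityError("similarity undefined for zero-norm vector")
    return float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))


def _pairwise_distance(P: np.ndarray) -> np.ndarray:
    n = P.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = 1.0 - uncentered_similarity(P[i], P[j])
    return D


def hierarchical_cluster(M: PhenotypePrevalenceMatrix) -> Dendrogram:
    """UPGMA agglomeration on d = 1 - uncentered similarity.

    Average linkage: the distance between two clusters is the arithmetic
    mean of all cross-pair distances, maintained incrementally as
    d(A+B, C) = (|A| d(A,C) + |B| d(B,C)) / (|A| + |B|).
    """
    n = len(M.diseases)
    if n < 2:
        raise ValueError("need at least 2 diseases to cluster")
    D = _pairwise_distance(M.P)
    # active clusters: node id -> size; dist keyed by frozen node ids
    size = {i: 1 for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): D[i, j] for i in range(n) for j in range(i + 1, n)
    }
    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        # lexicographic tie-break: smallest (a, b) among minimal distances
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), h = best
        new = next_id
        next_id += 1
        merges.append((a, b, max(h, 0.0), new))
        active.discard(a)
        active.discard(b)
        for c in sorted(active):
            da = dist.pop((min(a, c), max(a, c)))
            db = dist.pop((min(b, c), max(b, c)))
            dist[(c, new)] = (size[a] * da + size[b] * db) / (size[a] + size[b])
        del dist[(a, b)]
        size[new] = size[a] + size[b]
        active.add(new)
    # enforce monotone heights (UPGMA is monotone; guard against fp jitter)
    for k in range(1, len(merges)):
        a, b, h, new = merges[k]
        if h < merges[k - 1][2]:
            merges[k] = (a, b, merges[k - 1][2], new)
    return Dendrogram(leaves=list(M.diseases), merges=merges)


def cut_clusters(D: Dendrogram, k: int) -> np.ndarray:
    """Cut the tree into exactly ``k`` flat clusters.

    Applies the first n-k merges; labels are renumbered 0..k-1 in order of
    each cluster's smallest leaf index.
    """
    n = D.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b, _, new in D.merges[: n - k]:
        parent[find(a)] = new
        parent[find(b)] = new
    roots = [find(i) for i in range(n)]
    order: dict[int, int] = {}
    for r in roots:
        if r not in order:
            order[r] = len(order)
    return np.array([order[r] for r in roots], dtype=int)


def load_prevalence_tsv(path, impute: str | None = None) -> PhenotypePrevalenceMatrix:
    """Load a diseases x features prevalence TSV (first column = disease id).

    Missing values raise by default; ``impute='feature_mean'`` fills each
    feature's missing entries with that feature's mean.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        if impute == "feature_mean":
            df = df.fillna(df.mean(axis=0))
        else:
            raise ValueError(
                f"missing prevalences in {path}; pass impute='feature_mean' "
                "to fill with per-feature means"
            )
    return PhenotypePrevalenceMatrix(
        diseases=[str(i) for i in df.index],
        features=[str(c) for c in df.columns],
        P=df.to_numpy(dtype=float),
    )
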