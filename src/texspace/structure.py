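"""Model-level structure: hierarchical clustering and the SVD biplot.

The dendrogram is built on Euclidean distances between *rows* of the
model-similarity matrix (each model is represented by its similarity
profile to all models), agglomerated with unweighted average linkage
(UPGMA). The implementation is deliberately hand-rolled: the contract fixes
a deterministic lowest-index tie-break for equal linkage distances, which
library linkage routines do not guarantee. At m ≤ a few dozen models the
O(m³) loop is negligible.

The biplot factorizes the model × feature matrix ``F_mod = U Σ Vᵀ`` and
keeps three singular values; models are plotted from columns 2 and 3 of
``U₃`` and features from columns 2 and 3 of ``V₃``. The first column is
dropped because it tracks overall rating magnitude (how much of every
feature a model has / how often a feature is used), which carries no
contrast between models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Dendrogram",
    "SVDTriple",
    "BiplotCoords",
    "hca_dendrogram",
    "cut_dendrogram",
    "svd_embed",
    "biplot_coordinates",
    "to_newick",
]


@dataclass(frozen=True)
class Dendrogram:
    """Leaves plus ordered merges ``(cluster_a, cluster_b, height, size)``.

    Clusters 0..m-1 are the leaves; merge i creates cluster m+i, following
    the familiar linkage-matrix convention. Heights are non-decreasing along
    the merge order.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def linkage_matrix(self) -> np.ndarray:
        """Merges as an (m-1) × 4 scipy-style linkage matrix."""
        return np.asarray([[a, b, h, s] for a, b, h, s in self.merges],
                          dtype=float)


@dataclass(frozen=True)
class SVDTriple:
    """Rank-3 truncated SVD of the model × feature matrix."""

    U3: np.ndarray      # m × 3, orthonormal columns (models)
    Sigma3: np.ndarray  # 3 singular values, descending
    V3: np.ndarray      # 12 × 3, orthonormal columns (features)

    def reconstruct(self) -> np.ndarray:
        """Best rank-3 approximation of the decomposed matrix."""
        return self.U3 @ np.diag(self.Sigma3) @ self.V3.T


@dataclass(frozen=True)
class BiplotCoords:
    """Joint 2-D layout of models and features (U₃/V₃ columns 2 and 3)."""

    model_points: np.ndarray    # m × 2
    feature_points: np.ndarray  # 12 × 2
    model_labels: tuple[str, ...]
    feature_labels: tuple[str, ...]


def hca_dendrogram(S_mod: np.ndarray,
                   model_labels: Sequence[str] | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) dendrogram of model similarity profiles.

    Distance between two models is the Euclidean distance between their
    rows of ``S_mod``; ties in the minimum linkage distance break toward the
    lowest cluster-index pair, making the merge order fully deterministic.
    """
    S = np.asarray(S_mod, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S_mod must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S_mod must be symmetric")
    m = S.shape[0]
    if m < 2:
        raise ValueError("need at least 2 models")
    labels = tuple(model_labels) if model_labels is not None else \
        tuple(str(i) for i in range(m))
    if len(labels) != m:
        raise ValueError("model_labels length mismatch")

    diff = S[:, None, :] - S[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))

    members: dict[int, list[int]] = {i: [i] for i in range(m)}
    active = list(range(m))
    merges: list[tuple[int, int, float, int]] = []
    next_id = m
    while len(active) > 1:
        best_pair, best_d = None, np.inf
        for ia in range(len(active)):
            for ib in range(ia + 1, len(active)):
                a, b = active[ia], active[ib]
                d = dist[np.ix_(members[a], members[b])].mean()
                if d < best_d:  # strict < keeps the lowest-index pair on ties
                    best_pair, best_d = (a, b), d
        a, b = best_pair
        members[next_id] = members[a] + members[b]
        merges.append((a, b, float(best_d), len(members[next_id])))
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return Dendrogram(leaves=labels, merges=tuple(merges))


def cut_dendrogram(dendro: Dendrogram, level: float) -> list[list[str]]:
    """Partition of the leaves induced by merges strictly below ``level``.

    The defaults used in the analysis are 7.0 (major clusters) and 2.5
    (model merging); level 0 gives singletons, any level above the last
    merge height gives one cluster.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    m = dendro.n_leaves
    parent = list(range(2 * m - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (a, b, h, _) in enumerate(dendro.merges):
        if h < level:
            parent[find(a)] = parent[find(b)] = m + i
    clusters: dict[int, list[str]] = {}
    for leaf in range(m):
        clusters.setdefault(find(leaf), []).append(dendro.leaves[leaf])
    # stable ordering: clusters sorted by their first leaf's index
    return sorted(clusters.values(),
                  key=lambda c: dendro.leaves.index(c[0]))


def svd_embed(F_mod: np.ndarray) -> SVDTriple:
    """Rank-3 truncated SVD of the model × feature matrix."""
    F = np.asarray(F_mod, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValueError("F_mod must be finite")
    if not np.any(F):
        raise ValueError("F_mod is all zero (rank < 1)")
    U, s, Vt = np.linalg.svd(F, full_matrices=False)
    k = min(3, s.size)
    U3 = np.zeros((F.shape[0], 3))
    V3 = np.zeros((F.shape[1], 3))
    Sigma3 = np.zeros(3)
    U3[:, :k], Sigma3[:k], V3[:, :k] = U[:, :k], s[:k], Vt[:k].T
    return SVDTriple(U3=U3, Sigma3=Sigma3, V3=V3)


def biplot_coordinates(svd: SVDTriple,
                       model_labels: Sequence[str] | None = None) -> BiplotCoords:
    """Joint model/feature layout from singular-vector columns 2 and 3."""
    from .observer import FEATURE_NAMES
    m = svd.U3.shape[0]
    labels = tuple(model_labels) if model_labels is not None else \
        tuple(str(i) for i in range(m))
    return BiplotCoords(
        model_points=svd.U3[:, 1:3].copy(),
        feature_points=svd.V3[:, 1:3].copy(),
        model_labels=labels,
        feature_labels=FEATURE_NAMES,
    )


def _newick_node(dendro: Dendrogram, node: int, parent_h: float) -> str:
    m = dendro.n_leaves
    if node < m:
        name = dendro.leaves[node].replace(" ", "_")
        return f"{name}:{parent_h:.6g}"
    a, b, h, _ = dendro.merges[node - m]
    left = _newick_node(dendro, a, h - _node_height(dendro, a))
    right = _newick_node(dendro, b, h - _node_height(dendro, b))
    return f"({left},{right}):{max(parent_h - h, 0.0):.6g}"


def _node_height(dendro: Dendrogram, node: int) -> float:
    m = dendro.n_leaves
    return 0.0 if node < m else dendro.merges[node - m][2]


def to_newick(dendro: Dendrogram) -> str:
    """Newick string with merge heights as node depths (ultrametric tree)."""
    root = dendro.n_leaves + len(dendro.merges) - 1
    h = _node_height(dendro, root)
    a, b, _, _ = dendro.merges[-1]
    left = _newick_node(dendro, a, h - _node_height(dendro, a))
    right = _newick_node(dendro, b, h - _node_height(dendro, b))
    return f"({left},{right});"
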