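"""Perceptual texture space: Isomap embedding and dimension analysis.

The sample dissimilarity ``1 − S`` (co-grouping similarity complemented) is
embedded by Isomap: a symmetric k-nearest-neighbor graph weighted by the
dissimilarities, all-pairs shortest-path geodesics, then classical
(Torgerson) MDS of the geodesic matrix. Intrinsic dimensionality is read
off the residual-variance curve ``RV(d) = 1 − ρ²(geodesic, embedded
Euclidean distances)`` for d = 1..10, with the elbow located by the largest
second difference. Axes are interpreted by correlating each embedding
coordinate with each of the 12 averaged perceptual scales; the eight-subset
analysis repeats the embedding on sub-populations of models to check the
stability of the axis-feature pattern. Axis signs are arbitrary throughout
(an eigenvector and its negation are the same embedding), so pattern
comparisons use |r|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "DisconnectedGraphError",
    "IsomapEmbedding",
    "dissimilarity_from_similarity",
    "isomap_embed",
    "residual_variance_curve",
    "select_dimension",
    "axis_feature_correlations",
    "default_subset_definitions",
    "subset_analysis",
    "align_axes",
    "selected_feature_sets",
]


class DisconnectedGraphError(ValueError):
    """The k-NN graph is disconnected; carries the component count."""

    def __init__(self, n_components: int, k: int):
        self.n_components = n_components
        super().__init__(
            f"k-NN graph with k={k} has {n_components} connected components; "
            "increase k_neighbors")


@dataclass(frozen=True)
class IsomapEmbedding:
    """Embedding coordinates plus the geodesics and eigenvalues behind them."""

    coords: np.ndarray       # n × d, columns by descending eigenvalue
    eigenvalues: np.ndarray  # the d retained (positive) eigenvalues
    geodesics: np.ndarray    # n × n geodesic distance matrix


def dissimilarity_from_similarity(S: np.ndarray) -> np.ndarray:
    """Hollow symmetric dissimilarity ``1 − S`` with a zeroed diagonal."""
    D = 1.0 - np.asarray(S, dtype=float)
    np.fill_diagonal(D, 0.0)
    return D


def _validate_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("dissimilarity matrix must be hollow")
    return D


def _geodesics(D: np.ndarray, k_neighbors: int,
               bridge_components: bool = False) -> np.ndarray:
    n = D.shape[0]
    k = min(k_neighbors, n - 1)
    if k < 1:
        raise ValueError("k_neighbors must be >= 1")
    # dense masked adjacency: zero-weight edges (identical grouping
    # profiles are common in co-grouping data) must stay traversable,
    # which sparse formats silently drop
    edge = np.zeros((n, n), dtype=bool)
    order = np.argsort(D, axis=1, kind="stable")
    for i in range(n):
        nbrs = order[i][order[i] != i][:k]
        edge[i, nbrs] = True
    edge |= edge.T  # symmetrize: union of neighborhoods
    n_comp, comp = connected_components(csr_matrix(edge), directed=False)
    if n_comp > 1:
        if not bridge_components:
            raise DisconnectedGraphError(n_comp, k)
        # quantized dissimilarities can isolate whole blocks; greedily add
        # the smallest cross-component dissimilarity until connected
        while n_comp > 1:
            best, pair = np.inf, None
            for ci in range(n_comp):
                a = np.flatnonzero(comp == ci)
                b = np.flatnonzero(comp != ci)
                sub = D[np.ix_(a, b)]
                j = np.unravel_index(np.argmin(sub), sub.shape)
                if sub[j] < best:
                    best, pair = sub[j], (a[j[0]], b[j[1]])
            edge[pair[0], pair[1]] = edge[pair[1], pair[0]] = True
            n_comp, comp = connected_components(csr_matrix(edge), directed=False)
    graph = np.ma.MaskedArray(np.where(edge, D, 0.0), mask=~edge)
    return shortest_path(graph, method="D", directed=False)


def _torgerson(G: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    n = G.shape[0]
    G2 = G ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ G2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int(np.sum(evals > 1e-12))
    if d > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating "
                      f"embedding from d={d}", stacklevel=3)
        d = max(n_pos, 1)
    lam = np.clip(evals[:d], 0.0, None)
    return evecs[:, :d] * np.sqrt(lam), lam


def isomap_embed(D: np.ndarray, k_neighbors: int = 10, d: int = 3,
                 bridge_components: bool = False) -> IsomapEmbedding:
    """Isomap: symmetric k-NN graph → geodesics → classical MDS.

    With ``bridge_components=True`` a disconnected neighborhood graph is
    repaired by greedily adding the smallest cross-component dissimilarities
    instead of raising :class:`DisconnectedGraphError`.
    """
    D = _validate_dissimilarity(D)
    if d < 1:
        raise ValueError("d must be >= 1")
    G = _geodesics(D, k_neighbors, bridge_components)
    coords, lam = _torgerson(G, d)
    return IsomapEmbedding(coords=coords, eigenvalues=lam, geodesics=G)


def residual_variance_curve(D: np.ndarray, k_neighbors: int = 10,
                            max_dim: int = 10,
                            bridge_components: bool = False) -> np.ndarray:
    """``RV(d) = 1 − ρ²`` between geodesic and embedded distances, d = 1..max_dim."""
    D = _validate_dissimilarity(D)
    G = _geodesics(D, k_neighbors, bridge_components)
    coords, _ = _torgerson(G, min(max_dim, D.shape[0] - 1))
    iu = np.triu_indices(D.shape[0], k=1)
    g = G[iu]
    rv = np.empty(max_dim)
    for d in range(1, max_dim + 1):
        dd = min(d, coords.shape[1])
        diff = coords[:, None, :dd] - coords[None, :, :dd]
        emb = np.sqrt((diff ** 2).sum(axis=2))[iu]
        rho = np.corrcoef(g, emb)[0, 1]
        rv[d - 1] = 1.0 - rho ** 2
    return rv


def select_dimension(curve: np.ndarray) -> int:
    """Elbow of the residual-variance curve by largest second difference.

    Considers d in [2, len-1]; the second difference
    ``RV(d−1) − 2·RV(d) + RV(d+1)`` is maximal where the curve bends
    hardest; ties break toward the smaller dimension.
    """
    rv = np.asarray(curve, dtype=float)
    if rv.size < 4:
        raise ValueError("curve must have at least 4 entries")
    best_d, best_v = None, -np.inf
    for d in range(2, rv.size):  # d is 1-based dimension; rv[d-1] is RV(d)
        v = rv[d - 2] - 2.0 * rv[d - 1] + rv[d]
        if v > best_v + 1e-12:
            best_d, best_v = d, v
    return best_d


def axis_feature_correlations(coords: np.ndarray,
                              F_tex: np.ndarray) -> np.ndarray:
    """Pearson r between each embedding axis and each perceptual feature.

    Returns an (n_axes × 12) matrix; constant feature columns (or axes)
    yield r = 0 with a warning.
    """
    X = np.asarray(coords, dtype=float)
    F = np.asarray(F_tex, dtype=float)
    if X.shape[0] != F.shape[0]:
        raise ValueError("coords and F_tex must have matching n")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for correlations")
    out = np.zeros((X.shape[1], F.shape[1]))
    for a in range(X.shape[1]):
        xa = X[:, a]
        sx = xa.std()
        for j in range(F.shape[1]):
            fj = F[:, j]
            if sx == 0.0 or fj.std() == 0.0:
                warnings.warn(f"constant column (axis {a} / feature {j}); "
                              "correlation set to 0", stacklevel=2)
                continue
            out[a, j] = np.corrcoef(xa, fj)[0, 1]
    return out


def default_subset_definitions() -> list[list[str]]:
    """Eight stimulus subsets: excluded model families per subset.

    Subsets 1–7 drop, in turn: the forest-fire automaton, the weave model,
    all texton models, all cellular automata, the distance-field model, the
    folding models, and folding plus fusion models; subset 8 is the full set.
    """
    return [
        ["ca_forest_fire"],
        ["matrix_transformation"],
        ["texton_addition", "texton_probability_map", "texton_random_grid",
         "texton_random_walk", "texton_regular"],
        ["ca_forest_fire", "ca_surface_tension", "ca_excitable_media"],
        ["cellular"],
        ["folding_texton", "folding_cellular", "folding_fractal",
         "folding_perlin"],
        ["folding_texton", "folding_cellular", "folding_fractal",
         "folding_perlin", "fusion_cellular_texton", "fusion_perlin_cellular",
         "fusion_perlin_texton"],
        [],
    ]


def subset_analysis(S: np.ndarray, labels: Sequence[str], F_tex: np.ndarray,
                    subset_definitions: Sequence[Sequence[str]] | None = None,
                    k_neighbors: int = 10,
                    bridge_components: bool = False) -> list[np.ndarray]:
    """Axis-feature correlations re-computed on each stimulus subset.

    For each subset the sample similarity sub-matrix is extracted, re-embedded
    at d = 3 and correlated against the matching rows of ``F_tex``.
    """
    if subset_definitions is None:
        subset_definitions = default_subset_definitions()
    lab = np.asarray(labels, dtype=object)
    results = []
    for excluded in subset_definitions:
        keep = ~np.isin(lab, list(excluded))
        kept_models = set(lab[keep])
        if len(kept_models) < 3:
            raise ValueError(f"subset excluding {excluded} leaves "
                             f"{len(kept_models)} models (< 3)")
        idx = np.flatnonzero(keep)
        sub_S = np.asarray(S)[np.ix_(idx, idx)]
        emb = isomap_embed(dissimilarity_from_similarity(sub_S),
                           k_neighbors=k_neighbors, d=3,
                           bridge_components=bridge_components)
        results.append(axis_feature_correlations(emb.coords,
                                                 np.asarray(F_tex)[idx]))
    return results


def align_axes(corr: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Permute the rows of ``corr`` to best match ``reference`` rows.

    Greedy maximal-|r|-profile matching: axis pairs are matched in
    decreasing order of the dot product of their |r| profiles. Used to
    compare axis-feature patterns across embeddings whose axis order (and
    sign) is arbitrary.
    """
    C = np.abs(np.asarray(corr, dtype=float))
    R = np.abs(np.asarray(reference, dtype=float))
    k = C.shape[0]
    score = R @ C.T  # reference axes × candidate axes
    perm = [-1] * k
    used_ref, used_cand = set(), set()
    for _ in range(k):
        best, pair = -np.inf, None
        for i in range(k):
            if i in used_ref:
                continue
            for j in range(k):
                if j in used_cand:
                    continue
                if score[i, j] > best:
                    best, pair = score[i, j], (i, j)
        i, j = pair
        perm[i] = j
        used_ref.add(i)
        used_cand.add(j)
    return np.asarray(corr)[perm]


def selected_feature_sets(corr: np.ndarray,
                          threshold: float = 0.40) -> list[set[int]]:
    """Per-axis sets of feature indices with |r| at or above ``threshold``."""
    return [set(np.flatnonzero(np.abs(row) >= threshold))
            for row in np.asarray(corr)]
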