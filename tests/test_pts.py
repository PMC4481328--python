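import warnings

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import texspace as tx
from texspace.observer import default_loading_matrix, plant_latent_space
from texspace.pts import (DisconnectedGraphError, align_axes,
                          axis_feature_correlations,
                          default_subset_definitions,
                          dissimilarity_from_similarity, isomap_embed,
                          residual_variance_curve, select_dimension,
                          selected_feature_sets, subset_analysis)
from conftest import random_dissimilarity


def _embedded_distances(coords):
    return squareform(pdist(coords))


def test_line_embedding_is_exact():
    """Evenly spaced points on a line embed isometrically at d = 1."""
    x = np.linspace(0, 1, 12).reshape(-1, 1)
    D = _embedded_distances(x)
    emb = isomap_embed(D, k_neighbors=2, d=1)
    assert np.allclose(_embedded_distances(emb.coords), D, atol=1e-8)


def _oracle_isomap(D, k, d):
    """Independent oracle: explicit k-NN graph, Floyd-Warshall, direct MDS."""
    n = D.shape[0]
    G = np.full((n, n), np.inf)
    np.fill_diagonal(G, 0.0)
    for i in range(n):
        nbrs = np.argsort(D[i], kind="stable")
        nbrs = [j for j in nbrs if j != i][:k]
        for j in nbrs:
            G[i, j] = G[j, i] = D[i, j]
    for k_ in range(n):          # Floyd-Warshall
        for i in range(n):
            for j in range(n):
                if G[i, k_] + G[k_, j] < G[i, j]:
                    G[i, j] = G[i, k_] + G[k_, j]
    J = np.eye(n) - 1.0 / n
    B = -0.5 * J @ (G ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1][:d]
    lam = np.clip(evals[order], 0, None)
    return G, evecs[:, order] * np.sqrt(lam)


@pytest.mark.parametrize("seed", range(20))
def test_isomap_matches_bruteforce_oracle(seed):
    """Pipeline embedding distances equal Floyd-Warshall + eigh within 1e-8."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 21))
    D = random_dissimilarity(rng, n)
    emb = isomap_embed(D, k_neighbors=4, d=3)
    G, coords = _oracle_isomap(D, 4, 3)
    assert np.allclose(emb.geodesics, G, atol=1e-10)
    assert np.allclose(_embedded_distances(emb.coords),
                       _embedded_distances(coords), atol=1e-8)


def _two_blob_dissimilarity():
    pts = np.vstack([np.random.default_rng(0).normal(0, 0.1, (6, 2)),
                     np.random.default_rng(1).normal(10, 0.1, (6, 2))])
    D = _embedded_distances(pts)
    return D / D.max()


def test_disconnected_graph_raises_with_component_count():
    D = _two_blob_dissimilarity()
    with pytest.raises(DisconnectedGraphError) as exc:
        isomap_embed(D, k_neighbors=1, d=2)
    assert exc.value.n_components >= 2


def test_bridge_components_repairs_disconnection():
    D = _two_blob_dissimilarity()
    emb = isomap_embed(D, k_neighbors=1, d=2, bridge_components=True)
    assert np.isfinite(emb.coords).all()
    assert np.isfinite(emb.geodesics).all()


def test_full_graph_equals_classical_mds():
    """With k = n-1 the embedding coincides with classical MDS of D."""
    rng = np.random.default_rng(3)
    n = 12
    D = random_dissimilarity(rng, n, dim=4)
    emb = isomap_embed(D, k_neighbors=n - 1, d=4)
    J = np.eye(n) - 1.0 / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1][:4]
    coords = evecs[:, order] * np.sqrt(np.clip(evals[order], 0, None))
    assert np.allclose(emb.geodesics, D, atol=1e-10)
    assert np.allclose(_embedded_distances(emb.coords),
                       _embedded_distances(coords), atol=1e-8)


def test_residual_variance_exact_embedding_limit():
    """Data living exactly in 3 dimensions drives RV(3) to numerical zero."""
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(40, 3)) * [2.0, 1.5, 1.0]
    D = _embedded_distances(pts)
    rv = residual_variance_curve(D / D.max(), k_neighbors=39, max_dim=6)
    assert rv[2] <= 1e-8
    assert rv[0] > rv[2]


def test_residual_variance_nonincreasing():
    """RV decreases through the informative dimensions; the tail may wiggle
    within the noise floor (adding a noise eigenvector can nudge the
    distance correlation either way)."""
    for seed in range(4):
        rng = np.random.default_rng(seed)
        D = random_dissimilarity(rng, 30, dim=4)
        rv = residual_variance_curve(D, k_neighbors=8, max_dim=8)
        assert np.all(np.diff(rv[:4]) <= 1e-9)
        assert np.all(np.diff(rv) <= 3e-3)


def test_select_dimension_hand_curve():
    assert select_dimension([0.60, 0.30, 0.05, 0.04, 0.03]) == 3


def test_select_dimension_tie_breaks_small():
    assert select_dimension(np.linspace(0.5, 0.05, 10)) == 2


def test_select_dimension_short_curve_error():
    with pytest.raises(ValueError):
        select_dimension([0.5, 0.3, 0.1])


def test_axis_feature_correlations_basic():
    rng = np.random.default_rng(5)
    coords = rng.normal(size=(30, 3))
    F = rng.uniform(1, 9, (30, 12))
    F[:, 0] = coords[:, 0]  # feature equals an axis
    C = axis_feature_correlations(coords, F)
    assert C.shape == (3, 12)
    assert C[0, 0] == pytest.approx(1.0)
    neg = axis_feature_correlations(-coords, F)
    assert np.allclose(neg, -C, atol=1e-12)


def test_axis_feature_correlations_constant_column_warns():
    rng = np.random.default_rng(6)
    coords = rng.normal(size=(20, 2))
    F = rng.uniform(1, 9, (20, 12))
    F[:, 3] = 5.0
    with pytest.warns(UserWarning):
        C = axis_feature_correlations(coords, F)
    assert np.all(C[:, 3] == 0.0)


def test_axis_feature_correlations_errors():
    with pytest.raises(ValueError):
        axis_feature_correlations(np.zeros((5, 3)), np.zeros((6, 12)))
    with pytest.raises(ValueError):
        axis_feature_correlations(np.zeros((2, 3)), np.zeros((2, 12)))


@pytest.fixture(scope="module")
def small_study():
    ds = tx.build_dataset(tx.scaled_counts(120), with_heights=False)
    lat = plant_latent_space(ds, seed=0)
    recs = tx.simulate_grouping(lat, n_subjects=8, k_init=20, seed=1)
    S = tx.pooled_similarity(recs, len(ds))
    W = default_loading_matrix(3)
    R = tx.simulate_ratings(lat, W, n_subjects=12, seed=2)
    F = tx.sample_feature_matrix(R)
    return ds, S, F


def test_subset_full_set_equals_direct_analysis(small_study):
    ds, S, F = small_study
    direct = axis_feature_correlations(
        isomap_embed(dissimilarity_from_similarity(S), k_neighbors=10, d=3,
                     bridge_components=True).coords, F)
    via_subsets = subset_analysis(S, ds.labels, F, subset_definitions=[[]],
                                  k_neighbors=10, bridge_components=True)
    assert np.allclose(via_subsets[0], direct, atol=1e-12)


def test_subset_excluding_model_drops_its_samples(small_study):
    ds, S, F = small_study
    defs = default_subset_definitions()
    assert len(defs) == 8 and defs[-1] == []
    res = subset_analysis(S, ds.labels, F, subset_definitions=[["perlin_noise"]],
                          k_neighbors=10, bridge_components=True)
    assert res[0].shape == (3, 12)
    with pytest.raises(ValueError):
        keep2 = [m for m in tx.model_ids()[2:]]
        subset_analysis(S, ds.labels, F, subset_definitions=[keep2],
                        k_neighbors=10)


def test_align_axes_recovers_permutation():
    rng = np.random.default_rng(7)
    ref = rng.normal(size=(3, 12))
    perm = [2, 0, 1]
    aligned = align_axes(ref[perm], ref)
    assert np.allclose(aligned, ref)


def test_selected_feature_sets_threshold():
    corr = np.zeros((2, 12))
    corr[0, [1, 4]] = [0.5, -0.45]
    corr[1, 7] = 0.39
    sets = selected_feature_sets(corr, 0.4)
    assert sets[0] == {1, 4}
    assert sets[1] == set()
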