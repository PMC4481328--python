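import warnings

import numpy as np
import pytest

from texspace.mapping import (AxisFeatureSubsets, consistency_correlation,
                              fit_axis_regressors, loo_classify,
                              merge_model_classes, predict_pts,
                              select_axis_features)
from texspace.structure import hca_dendrogram


def test_select_axis_features_threshold_and_fallback():
    corr = np.zeros((3, 12))
    corr[0, [5, 8]] = [-0.74, -0.66]
    corr[1, [1, 3]] = [0.7, -0.8]
    corr[2, :] = 0.2
    with pytest.warns(UserWarning):
        subsets = select_axis_features(corr, threshold=0.40)
    assert subsets.subsets[0] == (5, 8)
    assert subsets.subsets[1] == (1, 3)
    assert len(subsets.subsets[2]) == 2  # top-2 fallback
    assert select_axis_features(corr, 0.0).subsets[2] == tuple(range(12))
    with pytest.raises(ValueError):
        select_axis_features(corr, 1.0)


def _linear_chain(n=200, seed=0):
    """Noiseless latent -> features -> coordinates, fully recoverable."""
    rng = np.random.default_rng(seed)
    z = np.clip(rng.normal(size=(n, 3)), -3, 3)
    W = np.zeros((3, 12))
    W[0, [5, 8]] = 0.5
    W[1, [1, 3]] = [0.5, -0.5]
    W[2, [0, 2]] = 0.5
    F = 5.0 + z @ W  # stays inside the Likert bounds, no clipping loss
    coords = (z - z.mean(0)) / z.std(0)
    subsets = AxisFeatureSubsets(((5, 8), (1, 3), (0, 2)))
    return F, coords, subsets


def test_regressors_recover_noiseless_chain():
    F, coords, subsets = _linear_chain()
    reg = fit_axis_regressors(F, coords, subsets, cv_folds=5, seed=0)
    assert np.all(reg.report.r_squared >= 0.99)
    assert np.all(reg.report.mse < 0.05)


def test_regressors_constant_target_degenerate():
    F, coords, subsets = _linear_chain(n=60)
    coords = coords.copy()
    coords[:, 1] = 0.0
    with pytest.warns(UserWarning):
        reg = fit_axis_regressors(F, coords, subsets, cv_folds=3, seed=0)
    assert reg.report.r_squared[1] == 0.0
    assert reg.report.mse[1] == pytest.approx(0.0, abs=1e-12)


def test_regressors_permuted_targets_near_zero():
    r2 = []
    for seed in range(10):
        F, coords, subsets = _linear_chain(n=100, seed=seed)
        rng = np.random.default_rng(seed + 100)
        shuffled = coords[rng.permutation(len(coords))]
        reg = fit_axis_regressors(F, shuffled, subsets, cv_folds=4, seed=seed)
        r2.append(reg.report.r_squared.mean())
    assert np.mean(r2) <= 0.1


def test_regressors_input_validation():
    F, coords, subsets = _linear_chain(n=30)
    with pytest.raises(ValueError):
        fit_axis_regressors(F, coords[:10], subsets)
    with pytest.raises(ValueError):
        fit_axis_regressors(F[:8], coords[:8], subsets, cv_folds=5)


def test_predict_pts_interface():
    F, coords, subsets = _linear_chain(n=80)
    reg = fit_axis_regressors(F, coords, subsets, cv_folds=4, seed=1)
    row = F[3]
    single = predict_pts(reg, row)
    assert single.shape == (3,)
    batch = predict_pts(reg, F[3:5])
    assert batch.shape == (2, 3)
    assert np.allclose(batch[0], single)
    # a training row reproduces the fitted value exactly
    fitted = reg.models[0].predict(
        reg.x_scalers[0].transform(row[list(subsets.subsets[0])].reshape(1, -1)))
    assert single[0] == pytest.approx(fitted[0])
    with pytest.raises(ValueError):
        predict_pts(reg, np.zeros(12))  # scale 0 outside Likert bounds
    with pytest.raises(ValueError):
        predict_pts(reg, np.full(11, 5.0))


def _dendro():
    rng = np.random.default_rng(0)
    S = rng.random((5, 5))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    return hca_dendrogram(S, [f"m{i}" for i in range(5)])


def test_merge_model_classes_levels():
    dendro = _dendro()
    ident = merge_model_classes(dendro, 0.0)
    assert len(set(ident.values())) == 5
    assert all(ident[m] == m for m in dendro.leaves)
    allin = merge_model_classes(dendro, dendro.merges[-1][2] + 1)
    assert len(set(allin.values())) == 1
    mid = merge_model_classes(dendro, dendro.merges[1][2] + 1e-9)
    assert len(set(mid.values())) == 3  # class count equals partition size


def test_loo_separable_classes_perfect():
    rng = np.random.default_rng(1)
    X = np.vstack([rng.normal(0, 0.2, (12, 2)), rng.normal(8, 0.2, (12, 2))])
    y = ["a"] * 12 + ["b"] * 12
    rep = loo_classify(X, y, seed=0)
    assert rep.accuracy == 1.0
    assert rep.confusion.sum() == 24
    assert np.trace(rep.confusion) == 24


def test_loo_shuffled_labels_at_chance():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(100, 3))
    y = [f"c{i % 5}" for i in range(100)]
    rep = loo_classify(X, y, seed=0)
    band = 2.58 * np.sqrt(0.2 * 0.8 / 100)
    assert abs(rep.accuracy - 0.2) <= band + 1e-9


def test_loo_singleton_class_flagged():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(11, 2))
    y = ["a"] * 5 + ["b"] * 5 + ["solo"]
    with pytest.warns(UserWarning):
        rep = loo_classify(X, y, seed=0)
    assert rep.singleton_classes == ("solo",)
    with pytest.raises(ValueError):
        loo_classify(X, ["a"] * 11)


def test_consistency_correlation_affine_map_is_one():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(30, 3))
    from scipy.spatial.distance import pdist, squareform
    d = squareform(pdist(X))
    S = 1.0 - 0.5 * d / d.max()  # distances an affine decreasing map of S
    np.fill_diagonal(S, 1.0)
    r = consistency_correlation(S, X)
    assert r == pytest.approx(1.0, abs=1e-10)


def test_consistency_correlation_null_near_zero():
    vals = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        S = rng.random((100, 100))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        rep = rng.normal(size=(100, 3))
        vals.append(consistency_correlation(S, rep))
    assert np.mean(vals) < 0.1


def test_consistency_correlation_degenerate_errors():
    S = np.eye(4)
    with pytest.raises(ValueError):
        consistency_correlation(S, np.ones((4, 2)))
    with pytest.raises(ValueError):
        consistency_correlation(S, np.ones((5, 2)) * np.arange(5)[:, None])


def test_recommend_interface(tiny_run):
    result, _ = tiny_run
    recs = result.recommend(np.full(12, 5.0))
    n_classes = len(set(result.class_map.values()))
    assert len(recs) == n_classes
    assert all(recs[i].score >= recs[i + 1].score for i in range(len(recs) - 1))
    seen = [m for r in recs for m in r.members]
    assert sorted(seen) == sorted(result.models)
    for rec in recs:
        for m in rec.members:
            assert rec.parameter_ranges[m]  # swept ranges attached
    with pytest.raises(ValueError):
        result.recommend(np.full(12, 0.5))


def test_recommend_centroid_self_consistency(default_run):
    """Scales at a model's rating centroid rank that model's class first."""
    result = default_run(0)
    labels = np.asarray(result.dataset.labels, dtype=object)
    hits, total = 0, 0
    for cls in sorted(set(result.class_map.values())):
        members = [m for m, c in result.class_map.items() if c == cls]
        mask = np.isin(labels, members)
        centroid = np.clip(result.F_tex[mask].mean(axis=0), 1, 9)
        top = result.recommend(centroid)[0]
        hits += top.class_label == cls
        total += 1
    assert hits / total >= 0.6
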