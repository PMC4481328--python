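"""From perceptual scales to the texture space, and back to generators.

Three kernel regressors (RBF support-vector regression with a small inner
grid search) map each axis's selected feature subset to that axis's
coordinate; embedding coordinates are standardized to zero mean and unit
variance per axis before fitting so mean-squared errors are comparable
across axes. A multiclass RBF support-vector classifier over merged model
classes (models joined below a dendrogram cut) supports leave-one-out
evaluation and, combined with the regressors, the recommendation endpoint:
user-given 12-feature Likert scales → predicted space coordinates → ranked
candidate generator classes with their member models and parameter ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr
from sklearn.model_selection import GridSearchCV, KFold, cross_val_predict
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .observer import FEATURE_NAMES
from .structure import Dendrogram, cut_dendrogram

__all__ = [
    "AxisFeatureSubsets",
    "AxisRegressors",
    "RegressionReport",
    "ClassificationReport",
    "Recommendation",
    "select_axis_features",
    "fit_axis_regressors",
    "predict_pts",
    "merge_model_classes",
    "loo_classify",
    "consistency_correlation",
    "recommend_model",
]

_SVR_GRID = {"C": [1.0, 10.0, 100.0], "gamma": ["scale", 0.1, 1.0]}
_SVC_GRID = {"C": [1.0, 10.0, 100.0], "gamma": ["scale", 0.1, 1.0]}


@dataclass(frozen=True)
class AxisFeatureSubsets:
    """Per-axis lists of selected feature indices (into FEATURE_NAMES)."""

    subsets: tuple[tuple[int, ...], ...]

    def names(self) -> list[list[str]]:
        return [[FEATURE_NAMES[i] for i in s] for s in self.subsets]


@dataclass
class RegressionReport:
    """Held-out per-axis fit quality on standardized coordinates."""

    mse: np.ndarray       # per axis
    r_squared: np.ndarray  # squared Pearson correlation per axis


@dataclass
class AxisRegressors:
    """Fitted per-axis regressors plus their scalers and selected features."""

    subsets: AxisFeatureSubsets
    models: list[SVR]
    x_scalers: list[StandardScaler]
    y_mean: np.ndarray
    y_sd: np.ndarray
    report: RegressionReport

    @property
    def n_axes(self) -> int:
        return len(self.models)


@dataclass
class ClassificationReport:
    """Leave-one-out accuracy plus the confusion matrix over classes."""

    accuracy: float
    confusion: np.ndarray
    class_labels: tuple[str, ...]
    singleton_classes: tuple[str, ...] = ()


@dataclass(frozen=True)
class Recommendation:
    """One ranked candidate class of generators for a scale query."""

    class_label: str
    score: float
    members: tuple[str, ...]
    parameter_ranges: Mapping[str, Mapping[str, tuple[float, float]]]


def select_axis_features(corr: np.ndarray,
                         threshold: float = 0.40) -> AxisFeatureSubsets:
    """Per axis, features with |r| ≥ threshold; top-2 fallback if none."""
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must be in [0, 1)")
    C = np.abs(np.asarray(corr, dtype=float))
    subsets = []
    for a, row in enumerate(C):
        sel = np.flatnonzero(row >= threshold)
        if sel.size == 0:
            warnings.warn(f"axis {a}: no feature reaches |r| >= {threshold}; "
                          "falling back to the top-2 features", stacklevel=2)
            sel = np.argsort(row)[::-1][:2]
        subsets.append(tuple(int(i) for i in sorted(sel)))
    return AxisFeatureSubsets(tuple(subsets))


def _grid_svr(X: np.ndarray, y: np.ndarray, cv: int, seed: int) -> SVR:
    grid = GridSearchCV(SVR(kernel="rbf"), _SVR_GRID,
                        cv=KFold(cv, shuffle=True, random_state=seed),
                        scoring="neg_mean_squared_error")
    grid.fit(X, y)
    return SVR(kernel="rbf", **grid.best_params_)


def fit_axis_regressors(F_tex: np.ndarray, coords: np.ndarray,
                        subsets: AxisFeatureSubsets, cv_folds: int = 5,
                        seed: int = 0) -> AxisRegressors:
    """Fit one RBF-SVR per axis on its selected feature subset.

    Coordinates are standardized per axis (stored for inversion); features
    are standardized per subset. The report carries held-out MSE and squared
    Pearson correlation from ``cv_folds``-fold cross-validated predictions.
    """
    F = np.asarray(F_tex, dtype=float)
    Y = np.asarray(coords, dtype=float)
    n = F.shape[0]
    if Y.shape[0] != n:
        raise ValueError("F_tex and coords must have matching n")
    if n < 2 * cv_folds:
        raise ValueError("need n >= 2·cv_folds samples")
    n_axes = Y.shape[1]
    if len(subsets.subsets) != n_axes:
        raise ValueError("one feature subset required per axis")

    y_mean, y_sd = Y.mean(axis=0), Y.std(axis=0)
    models, scalers = [], []
    mse = np.zeros(n_axes)
    r2 = np.zeros(n_axes)
    for a in range(n_axes):
        Xa = F[:, list(subsets.subsets[a])]
        scaler = StandardScaler().fit(Xa)
        Xs = scaler.transform(Xa)
        if y_sd[a] == 0.0:
            warnings.warn(f"axis {a}: constant coordinate target; squared "
                          "correlation reported as 0", stacklevel=2)
            ys = Y[:, a] - y_mean[a]
            model = SVR(kernel="rbf").fit(Xs, ys)
            models.append(model)
            scalers.append(scaler)
            continue
        ys = (Y[:, a] - y_mean[a]) / y_sd[a]
        model = _grid_svr(Xs, ys, cv_folds, seed)
        pred = cross_val_predict(model, Xs, ys,
                                 cv=KFold(cv_folds, shuffle=True,
                                          random_state=seed))
        mse[a] = float(np.mean((pred - ys) ** 2))
        if np.std(pred) > 0:
            r2[a] = float(pearsonr(pred, ys)[0] ** 2)
        models.append(model.fit(Xs, ys))
        scalers.append(scaler)
    return AxisRegressors(subsets=subsets, models=models, x_scalers=scalers,
                          y_mean=y_mean, y_sd=y_sd,
                          report=RegressionReport(mse=mse, r_squared=r2))


def _check_scales(scales: np.ndarray) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(scales, dtype=float))
    if arr.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"scales must have {len(FEATURE_NAMES)} values")
    if np.any(arr < 1.0) or np.any(arr > 9.0):
        raise ValueError("scales must lie within the Likert bounds [1, 9]")
    return arr


def predict_pts(regressors: AxisRegressors, scales: np.ndarray,
                standardized: bool = True) -> np.ndarray:
    """Predict space coordinates from 12-feature scale vectors (row-wise).

    With ``standardized=False`` predictions are mapped back to the original
    coordinate scale of the embedding used at fit time.
    """
    arr = _check_scales(scales)
    cols = []
    for a in range(regressors.n_axes):
        Xa = arr[:, list(regressors.subsets.subsets[a])]
        p = regressors.models[a].predict(regressors.x_scalers[a].transform(Xa))
        if not standardized:
            sd = regressors.y_sd[a] if regressors.y_sd[a] > 0 else 1.0
            p = p * sd + regressors.y_mean[a]
        cols.append(p)
    out = np.stack(cols, axis=1)
    return out[0] if np.asarray(scales).ndim == 1 else out


def merge_model_classes(dendro: Dendrogram, level: float = 2.5) -> dict[str, str]:
    """Map each model to its merged-class label at a dendrogram cut.

    Class labels are the member model ids joined with '+', in leaf order;
    ordering is stable across runs.
    """
    partition = cut_dendrogram(dendro, level)
    out: dict[str, str] = {}
    for cluster in partition:
        label = "+".join(cluster)
        for m in cluster:
            out[m] = label
    return out


def loo_classify(features: np.ndarray, classes: Sequence[str],
                 seed: int = 0, cv_folds: int = 5) -> ClassificationReport:
    """Leave-one-out multiclass RBF-SVC accuracy and confusion matrix.

    Hyperparameters are chosen once by grid search on the full data, then
    each sample is predicted by a classifier trained on the others.
    Singleton classes are kept (they cannot be predicted correctly by
    construction) and flagged in the report.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(classes, dtype=object)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and classes must have matching n")
    labels, counts = np.unique(y, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 classes")
    singletons = tuple(labels[counts == 1])
    if singletons:
        warnings.warn(f"singleton classes present: {singletons}", stacklevel=2)

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    folds = min(cv_folds, int(counts.min())) if counts.min() >= 2 else 2
    folds = max(2, folds)
    grid = GridSearchCV(SVC(kernel="rbf"), _SVC_GRID,
                        cv=KFold(folds, shuffle=True, random_state=seed))
    grid.fit(Xs, y)
    params = grid.best_params_

    n = X.shape[0]
    pred = np.empty(n, dtype=object)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        clf = SVC(kernel="rbf", **params).fit(Xs[train], y[train])
        pred[i] = clf.predict(Xs[i:i + 1])[0]
    accuracy = float(np.mean(pred == y))
    lab_index = {l: k for k, l in enumerate(labels)}
    confusion = np.zeros((labels.size, labels.size), dtype=int)
    for t, p in zip(y, pred):
        confusion[lab_index[t], lab_index.get(p, 0)] += 1
    return ClassificationReport(accuracy=accuracy, confusion=confusion,
                                class_labels=tuple(labels),
                                singleton_classes=singletons)


def consistency_correlation(S: np.ndarray, representation: np.ndarray) -> float:
    """|Pearson r| between similarities and representation distances.

    Correlates the strict upper triangle of ``S`` with the pairwise
    Euclidean distances of the representation; the magnitude is reported
    because a similarity-vs-distance correlation is negative by nature.
    """
    S = np.asarray(S, dtype=float)
    X = np.asarray(representation, dtype=float)
    if S.shape[0] != X.shape[0]:
        raise ValueError("S and representation must have matching n")
    d = pdist(X)
    if d.std() == 0.0:
        raise ValueError("representation is degenerate (all points coincide)")
    iu = np.triu_indices(S.shape[0], k=1)
    return float(abs(pearsonr(S[iu], d)[0]))


def recommend_model(user_scales: np.ndarray, regressors: AxisRegressors,
                    classifier: SVC, class_scaler: StandardScaler,
                    class_map: Mapping[str, str],
                    parameter_ranges: Mapping[str, Mapping[str, tuple[float, float]]],
                    ) -> list[Recommendation]:
    """Rank generator classes for user-given perceptual scales.

    Predicts space coordinates from the scales, scores every merged class
    with the fitted classifier's decision function, and returns all classes
    ranked by score (ties: larger class first, then label). Each entry
    carries the member models and their swept parameter ranges.
    """
    arr = _check_scales(user_scales)
    coords = predict_pts(regressors, arr[0])
    z = class_scaler.transform(coords.reshape(1, -1))
    scores = classifier.decision_function(z)[0]
    classes = list(classifier.classes_)
    if np.ndim(scores) == 0:  # binary: single margin
        scores = np.array([-float(scores), float(scores)])

    members: dict[str, list[str]] = {}
    for model, cls in class_map.items():
        members.setdefault(cls, []).append(model)

    order = sorted(
        range(len(classes)),
        key=lambda i: (-scores[i], -len(members.get(classes[i], [])),
                       str(classes[i])))
    out = []
    for i in order:
        cls = classes[i]
        mem = tuple(members.get(cls, ()))
        out.append(Recommendation(
            class_label=str(cls), score=float(scores[i]), members=mem,
            parameter_ranges={m: parameter_ranges[m] for m in mem
                              if m in parameter_ranges}))
    return out
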