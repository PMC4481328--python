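"""Pipeline orchestration, configuration and artifact export.

``run_full_pipeline`` executes the whole study on synthetic observers:
texture generation → (optional) rendering → latent-space planting →
grouping/rating simulation → similarity and feature matrices → dendrogram +
SVD biplot → Isomap space with dimension selection and axis-feature
correlations → per-axis regressors, merged-class leave-one-out
classification, consistency correlations — everything derived
deterministically from one master seed.

Dendrogram cuts deserve a note: :func:`texspace.structure.cut_dendrogram`
exposes absolute levels, but the pipeline expresses its two cuts as
fractions of the maximum merge height (defaults 0.85 for the major clusters
and 0.30 for model merging). The absolute heights of an average-linkage
tree scale with the spread of the similarity profiles, which differs
between observer populations; relative cuts keep the two levels meaningful
across configurations while preserving their ratio to the tree height.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import mapping as mp
from . import observer as ob
from . import percepdata as pc
from . import pts as ps
from . import render as rd
from . import structure as st
from . import texgen as tg
from ._seeds import child_seed

__all__ = ["PipelineConfig", "PipelineResult", "RunReport",
           "run_full_pipeline", "export_artifacts",
           "write_matrix_csv", "read_matrix_csv"]


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic study.

    Defaults mirror the study conditions: 20 grouping subjects, 58 rating
    subjects, 12 features on 9-point scales, a 3-D planted space, Isomap
    over dimensions 1..10, |r| >= 0.4 feature selection. The default
    texture budget is 200 samples across all 23 models at 128 px — the
    package's working scale; ``counts = full_default_counts()`` with
    ``size=512`` reproduces the full 450-sample configuration. ``k_init``
    is capped at n/5 at run time so small configurations stay valid.
    """

    counts: Mapping[str, int] = field(default_factory=lambda: tg.scaled_counts(200))
    size: int = 128
    master_seed: int = 0
    # rendering
    render_images: bool = False
    slant: float = 45.0
    tilt: float = 135.0
    albedo: float = 1.0
    # observer
    latent_dim: int = 3
    center_scale: float | Sequence[float] | None = None
    spread: float | Sequence[float] | None = None
    sweep_drift: float = 1.2
    n_grouping_subjects: int = 20
    n_rating_subjects: int = 58
    perceptual_noise: float = 0.55
    rating_noise: float = 1.0
    rating_sample_noise: float = 1.0
    k_init: int = 40
    # analysis
    k_neighbors: int = 25
    bridge_components: bool = True
    max_dims: int = 10
    corr_threshold: float = 0.40
    cut_major_frac: float = 0.85
    cut_merge_frac: float = 0.30
    cv_folds: int = 5
    # generation scope
    with_heights: bool = False
    out_dir: str | None = None

    def validate(self) -> None:
        if not self.counts or len(self.counts) < 2:
            raise ValueError("config must name at least 2 models")
        for m in self.counts:
            tg.get_model(m)  # raises on unregistered ids
        if self.master_seed < 0:
            raise ValueError("master_seed must be non-negative")
        for name in ("cut_major_frac", "cut_merge_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PipelineResult:
    """Everything the pipeline computes, ready for export or recommendation."""

    config: PipelineConfig
    dataset: tg.TextureDataset
    latent: ob.LatentCoords
    grouping_records: list[ob.GroupingRecord]
    ratings: np.ndarray
    S: np.ndarray
    S_mod: np.ndarray
    models: list[str]
    F_tex: np.ndarray
    F_mod: np.ndarray
    dendrogram: st.Dendrogram
    major_clusters: list[list[str]]
    svd: st.SVDTriple
    biplot: st.BiplotCoords
    rv_curve: np.ndarray
    selected_dim: int
    embedding: ps.IsomapEmbedding
    axis_corr: np.ndarray
    subsets: mp.AxisFeatureSubsets
    regressors: mp.AxisRegressors
    class_map: dict[str, str]
    merge_level: float
    loo_pts: mp.ClassificationReport
    loo_features: mp.ClassificationReport
    consistency_pts: float
    consistency_features: float
    pts_classifier: SVC
    pts_class_scaler: StandardScaler
    seeds: dict[str, int]
    images: list | None = None

    def recommend(self, user_scales: np.ndarray) -> list[mp.Recommendation]:
        """Rank generator classes for a 12-value perceptual-scale query."""
        ranges = {m: dict(tg.get_model(m).params) for m in self.models}
        return mp.recommend_model(user_scales, self.regressors,
                                  self.pts_classifier, self.pts_class_scaler,
                                  self.class_map, ranges)


@dataclass
class RunReport:
    """Stage summaries, derived seeds and exported-file manifest."""

    seeds: dict[str, int]
    stages: dict[str, dict]
    files: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"seeds": self.seeds, "stages": self.stages,
                           "files": self.files}, indent=1)


def _coords_std(coords: np.ndarray) -> np.ndarray:
    sd = coords.std(axis=0)
    sd[sd == 0] = 1.0
    return (coords - coords.mean(axis=0)) / sd


def run_full_pipeline(config: PipelineConfig | None = None) -> tuple[PipelineResult, RunReport]:
    """Run the whole synthetic study; deterministic in (config, master_seed)."""
    config = config or PipelineConfig()
    config.validate()
    seeds = {name: child_seed(config.master_seed, name)
             for name in ("dataset", "latent", "grouping", "rating", "analysis")}
    stages: dict[str, dict] = {}

    dataset = tg.build_dataset(config.counts, size=config.size,
                               master_seed=seeds["dataset"],
                               with_heights=config.with_heights)
    stages["texgen"] = {"n_samples": len(dataset),
                        "n_models": len(set(dataset.labels)),
                        "size": config.size}

    if config.render_images and config.with_heights:
        light = rd.LightConfig(slant=config.slant, tilt=config.tilt,
                               albedo=config.albedo)
        images = [rd.render_lambertian(hm, light) for hm in dataset.samples]
        stages["render"] = {"n_images": len(images),
                            "slant": config.slant, "tilt": config.tilt}
    else:
        images = None
        stages["render"] = {"n_images": 0}

    latent = ob.plant_latent_space(dataset, D=config.latent_dim,
                                   center_scale=config.center_scale,
                                   spread=config.spread,
                                   sweep_drift=config.sweep_drift,
                                   seed=seeds["latent"])
    loadings = ob.default_loading_matrix(config.latent_dim)
    # cap initial groups at n/5 so small configurations stay valid
    k_init = max(2, min(config.k_init, len(dataset) // 5))
    records = ob.simulate_grouping(latent,
                                   n_subjects=config.n_grouping_subjects,
                                   perceptual_noise=config.perceptual_noise,
                                   k_init=k_init,
                                   seed=seeds["grouping"])
    ratings = ob.simulate_ratings(latent, loadings,
                                  noise_sd=config.rating_noise,
                                  n_subjects=config.n_rating_subjects,
                                  seed=seeds["rating"],
                                  sample_noise_sd=config.rating_sample_noise)
    stages["observer"] = {"n_grouping_subjects": len(records),
                          "n_rating_subjects": ratings.shape[0],
                          "latent_dim": config.latent_dim}

    n = len(dataset)
    S = pc.pooled_similarity(records, n)
    S_mod, models = pc.model_similarity(S, dataset.labels)
    F_tex = pc.sample_feature_matrix(ratings)
    F_mod, _ = pc.model_feature_matrix(F_tex, dataset.labels)
    stages["percepdata"] = {"S": list(S.shape), "S_mod": list(S_mod.shape),
                            "F_tex": list(F_tex.shape),
                            "F_mod": list(F_mod.shape)}

    dendro = st.hca_dendrogram(S_mod, models)
    max_h = dendro.merges[-1][2]
    cut_major = config.cut_major_frac * max_h
    merge_level = config.cut_merge_frac * max_h
    major = st.cut_dendrogram(dendro, cut_major)
    svd = st.svd_embed(F_mod)
    biplot = st.biplot_coordinates(svd, models)
    stages["structure"] = {"max_height": float(max_h),
                           "n_major_clusters": len(major),
                           "singular_values": svd.Sigma3.tolist()}

    D = ps.dissimilarity_from_similarity(S)
    rv = ps.residual_variance_curve(D, k_neighbors=config.k_neighbors,
                                    max_dim=config.max_dims,
                                    bridge_components=config.bridge_components)
    sel = ps.select_dimension(rv)
    emb = ps.isomap_embed(D, k_neighbors=config.k_neighbors, d=3,
                          bridge_components=config.bridge_components)
    corr = ps.axis_feature_correlations(emb.coords, F_tex)
    stages["pts"] = {"selected_dim": int(sel),
                     "rv": [float(v) for v in rv],
                     "n_axes": int(emb.coords.shape[1])}

    subsets = mp.select_axis_features(corr, threshold=config.corr_threshold)
    coords_std = _coords_std(emb.coords)
    regressors = mp.fit_axis_regressors(F_tex, coords_std, subsets,
                                        cv_folds=config.cv_folds,
                                        seed=seeds["analysis"])
    class_map = mp.merge_model_classes(dendro, merge_level)
    classes = [class_map[m] for m in dataset.labels]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loo_pts = mp.loo_classify(coords_std, classes, seed=seeds["analysis"])
        loo_feat = mp.loo_classify(F_tex, classes, seed=seeds["analysis"])
    cons_pts = mp.consistency_correlation(S, coords_std)
    cons_feat = mp.consistency_correlation(S, F_tex)

    scaler = StandardScaler().fit(coords_std)
    clf = SVC(kernel="rbf", C=10.0).fit(scaler.transform(coords_std), classes)
    stages["mapping"] = {
        "merge_level": float(merge_level),
        "n_classes": len(set(class_map.values())),
        "loo_accuracy_pts": loo_pts.accuracy,
        "loo_accuracy_features": loo_feat.accuracy,
        "consistency_r_pts": cons_pts,
        "consistency_r_features": cons_feat,
        "regression_mse": regressors.report.mse.tolist(),
        "regression_r2": regressors.report.r_squared.tolist(),
    }

    result = PipelineResult(
        config=config, dataset=dataset, latent=latent,
        grouping_records=records, ratings=ratings, S=S, S_mod=S_mod,
        models=models, F_tex=F_tex, F_mod=F_mod, dendrogram=dendro,
        major_clusters=major, svd=svd, biplot=biplot, rv_curve=rv,
        selected_dim=sel, embedding=emb, axis_corr=corr, subsets=subsets,
        regressors=regressors, class_map=class_map, merge_level=merge_level,
        loo_pts=loo_pts, loo_features=loo_feat, consistency_pts=cons_pts,
        consistency_features=cons_feat, pts_classifier=clf,
        pts_class_scaler=scaler, seeds=seeds, images=images)
    report = RunReport(seeds=seeds, stages=stages)

    if config.out_dir is not None:
        export_artifacts(result, report, config.out_dir, images=images)
    return result, report


# ---------------------------------------------------------------------------
# export

def write_matrix_csv(M: np.ndarray, path: str | Path,
                     row_labels: Sequence[str] | None = None,
                     col_labels: Sequence[str] | None = None) -> None:
    """Write a matrix as CSV with identifier headers, full float precision."""
    M = np.asarray(M)
    rows = row_labels if row_labels is not None else [str(i) for i in range(M.shape[0])]
    cols = col_labels if col_labels is not None else [str(j) for j in range(M.shape[1])]
    df = pd.DataFrame(M, index=list(rows), columns=list(cols))
    df.to_csv(path, float_format="%.17g")


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a matrix CSV back; returns (matrix, row_labels, col_labels)."""
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], \
        [str(c) for c in df.columns]


def export_artifacts(result: PipelineResult, report: RunReport,
                     directory: str | Path, images=None) -> list[str]:
    if images is None:
        images = result.images
    """Write all pipeline artifacts; returns the file manifest.

    Matrices go to CSV with headers (round-trip exact to 1e-12), grouping
    records and the run report to JSON, the dendrogram to Newick, height
    maps and renders to 16-bit/8-bit PNG when present.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def note(p: Path):
        files.append(str(p.relative_to(directory)))

    n = len(result.dataset)
    sample_ids = [f"s{i:04d}" for i in range(n)]
    feat = list(ob.FEATURE_NAMES)
    axes = [f"axis{k + 1}" for k in range(result.axis_corr.shape[0])]

    items = [
        ("S.csv", result.S, sample_ids, sample_ids),
        ("S_mod.csv", result.S_mod, result.models, result.models),
        ("F_tex.csv", result.F_tex, sample_ids, feat),
        ("F_mod.csv", result.F_mod, result.models, feat),
        ("pts_coords.csv", result.embedding.coords, sample_ids,
         axes[:result.embedding.coords.shape[1]]),
        ("residual_variance.csv", result.rv_curve.reshape(-1, 1),
         [f"d{d}" for d in range(1, result.rv_curve.size + 1)], ["rv"]),
        ("axis_feature_correlations.csv", result.axis_corr, axes, feat),
        ("biplot_models.csv", result.biplot.model_points, result.models,
         ["dim2", "dim3"]),
        ("biplot_features.csv", result.biplot.feature_points, feat,
         ["dim2", "dim3"]),
    ]
    for name, M, r, c in items:
        p = directory / name
        write_matrix_csv(M, p, r, c)
        note(p)

    p = directory / "dendrogram.nwk"
    p.write_text(st.to_newick(result.dendrogram) + "\n")
    note(p)
    p = directory / "dendrogram_merges.csv"
    write_matrix_csv(result.dendrogram.linkage_matrix(), p,
                     [f"merge{i}" for i in range(len(result.dendrogram.merges))],
                     ["cluster_a", "cluster_b", "height", "size"])
    note(p)

    groups = [{
        "subject": r_.subject,
        "initial_partition": [list(g) for g in r_.initial_partition],
        "merges": [list(mg) for mg in r_.merges],
    } for r_ in result.grouping_records]
    p = directory / "grouping_records.json"
    p.write_text(json.dumps({"feature_schema": feat, "records": groups}))
    note(p)

    p = directory / "evaluation.json"
    p.write_text(json.dumps({
        "feature_schema": feat,
        "selected_dimension": int(result.selected_dim),
        "merge_level": result.merge_level,
        "class_map": result.class_map,
        "loo_accuracy_pts": result.loo_pts.accuracy,
        "loo_accuracy_features": result.loo_features.accuracy,
        "consistency_r_pts": result.consistency_pts,
        "consistency_r_features": result.consistency_features,
        "regression_mse": result.regressors.report.mse.tolist(),
        "regression_r2": result.regressors.report.r_squared.tolist(),
    }, indent=1))
    note(p)

    for rep, name in ((result.loo_pts, "confusion_pts.csv"),
                      (result.loo_features, "confusion_features.csv")):
        p = directory / name
        write_matrix_csv(rep.confusion, p, list(rep.class_labels),
                         list(rep.class_labels))
        note(p)

    tg.write_manifest(result.dataset, directory / "manifest.json")
    note(directory / "manifest.json")

    if result.dataset.samples is not None:
        img_dir = directory / "heightmaps"
        img_dir.mkdir(exist_ok=True)
        for i, hm in enumerate(result.dataset.samples):
            p = img_dir / f"{sample_ids[i]}.png"
            tg.export_height_map(hm, p)
            note(p)
    if images is not None:
        img_dir = directory / "renders"
        img_dir.mkdir(exist_ok=True)
        for i, img in enumerate(images):
            p = img_dir / f"{sample_ids[i]}.png"
            rd.export_image(img, p)
            note(p)

    report.files = files
    p = directory / "run_report.json"
    p.write_text(report.to_json())
    return files
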