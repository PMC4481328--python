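"""Model-level structure: dendrogram cuts and the SVD biplot.

Runs the grouping/rating simulation, clusters the 23 models by their
similarity profiles (UPGMA), cuts the tree into major clusters and merged
classes, and factorizes the model-feature matrix into a joint biplot.
"""

import warnings

import numpy as np

import texspace as tx
from texspace.workbench import PipelineConfig, run_full_pipeline

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result, _ = run_full_pipeline(PipelineConfig(master_seed=0))

print("major clusters (cut at 85% of tree height):")
for i, cluster in enumerate(result.major_clusters):
    print(f"  cluster {chr(65 + i)}: {', '.join(cluster)}")

classes = sorted(set(result.class_map.values()))
merged = [c for c in classes if "+" in c]
print(f"\nmerged classes at the low cut: {len(classes)} classes, "
      f"{len(merged)} of them multi-model:")
for c in merged:
    print(f"  {c}")

svd = result.svd
share = svd.Sigma3 ** 2 / np.sum(np.linalg.svd(result.F_mod, compute_uv=False) ** 2)
print(f"\nSVD: top-3 singular values {np.round(svd.Sigma3, 2)} "
      f"({100 * share.sum():.1f}% of Frobenius energy)")
# biplot: models near a feature point exhibit that feature strongly
bp = result.biplot
j = list(bp.feature_labels).index("regularity")
d = np.linalg.norm(bp.model_points - bp.feature_points[j], axis=1)
order = np.argsort(d)[:3]
print("models closest to the 'regularity' feature point:",
      ", ".join(bp.model_labels[i] for i in order))
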