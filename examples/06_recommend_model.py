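"""Recommend procedural generators from user-given perceptual scales.

Fits the full pipeline, then asks: which generator family produces a
texture that is highly repetitive, regular, oriented and uniform (a woven
or ornamental look)? And which produces something random and granular?
"""

import warnings

import numpy as np

import texspace as tx
from texspace.observer import FEATURE_NAMES
from texspace.workbench import PipelineConfig, run_full_pipeline

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result, _ = run_full_pipeline(PipelineConfig(master_seed=0))

print(f"LOO accuracy over {len(set(result.class_map.values()))} merged "
      f"classes: {100 * result.loo_pts.accuracy:.1f}% with 3 space "
      f"dimensions vs {100 * result.loo_features.accuracy:.1f}% with the "
      "12 raw scales")
print(f"consistency |r| with grouping similarity: "
      f"{result.consistency_pts:.3f} (space) vs "
      f"{result.consistency_features:.3f} (raw scales)\n")


def ask(description, **scales):
    query = np.full(12, 5.0)
    for name, value in scales.items():
        query[FEATURE_NAMES.index(name)] = value
    top = result.recommend(query)[:2]
    print(description)
    for rank, rec in enumerate(top, 1):
        print(f"  {rank}. {rec.class_label} (score {rec.score:.2f})")
    print()


ask("ordered / woven look (repetitive, regular, oriented, uniform, non-random):",
    repetition=8, regularity=8, **{"local orientation": 8, "uniformity": 8},
    randomness=2)
ask("granular random field (random, granular, dense, fine):",
    randomness=8, granularity=8, **{"feature density": 8, "coarseness": 8})
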