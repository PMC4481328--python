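"""Simulate the grouping and rating experiments on a planted latent space.

Plants 3-D perceptual coordinates for a 200-texture dataset, simulates 20
grouping observers and 58 Likert raters, and builds the four core matrices:
sample and model similarity (S, S_mod) and sample and model features
(F_tex, F_mod).
"""

import numpy as np

import texspace as tx
from texspace.observer import FEATURE_NAMES, default_loading_matrix

dataset = tx.build_dataset(tx.scaled_counts(200), with_heights=False)
latent = tx.plant_latent_space(dataset, D=3, seed=0)
print(f"planted {latent.coords.shape[0]} samples in {latent.D}-D, "
      f"axis sds {np.round(latent.coords.std(axis=0), 2)}")

records = tx.simulate_grouping(latent, n_subjects=20, k_init=40, seed=1)
sizes = [len(r.initial_partition) for r in records]
print(f"grouping: {len(records)} subjects, initial groups "
      f"{min(sizes)}-{max(sizes)}, merges recorded down to one cluster")

S = tx.pooled_similarity(records, len(dataset))
S_mod, models = tx.model_similarity(S, dataset.labels)
print(f"S {S.shape}, entries in [{S.min():.2f}, {S.max():.2f}]; "
      f"S_mod {S_mod.shape}")
# high diagonal blocks = subjects group same-model textures together
within = np.mean(np.diag(S_mod))
between = S_mod[~np.eye(len(models), dtype=bool)].mean()
print(f"mean within-model similarity {within:.3f} vs between {between:.3f}")

ratings = tx.simulate_ratings(latent, default_loading_matrix(3),
                              n_subjects=58, seed=2)
F_tex = tx.sample_feature_matrix(ratings)
F_mod, _ = tx.model_feature_matrix(F_tex, dataset.labels)
j = FEATURE_NAMES.index("feature density")
print(f"F_tex {F_tex.shape} in [{F_tex.min():.1f}, {F_tex.max():.1f}]; "
      f"'feature density' spans {F_tex[:, j].min():.1f}-{F_tex[:, j].max():.1f}")
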