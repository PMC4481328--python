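"""Core matrices built from grouping records and ratings.

Four matrices drive the whole analysis:

* ``S`` — pooled sample similarity: for each subject, co-grouping is counted
  over the stage partitions (the initial partition plus the partition after
  each recorded merge, excluding the final all-in-one stage — counting the
  trivial stage would give every pair positive similarity and make the
  stated 0..1 range unreachable); ``s_ij`` is the fraction of counted stages
  in which i and j share a group, averaged over subjects. Diagonal fixed at 1.
* ``S_mod`` — model-level similarity: block averages of ``S`` over sample
  pairs of each model pair; within-model blocks exclude the diagonal.
* ``F_tex`` — sample × 12 feature matrix: Likert ratings averaged over the
  subjects who rated each sample (missing ratings are NaN in the tensor).
* ``F_mod`` — model × 12 feature matrix: rows of ``F_tex`` averaged per model.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .observer import FEATURE_NAMES, GroupingRecord

__all__ = [
    "pooled_similarity",
    "model_similarity",
    "sample_feature_matrix",
    "model_feature_matrix",
    "unique_models",
]


def unique_models(labels: Sequence[str]) -> list[str]:
    """Model ids in order of first appearance."""
    return list(dict.fromkeys(labels))


def _subject_similarity(record: GroupingRecord, n: int) -> np.ndarray:
    stages = record.stage_partitions()
    if len(stages) >= 2 and len(stages[-1]) == 1:
        stages = stages[:-1]  # drop the trivial all-in-one stage
    if not stages:
        raise ValueError("record has zero countable stages")
    S = np.zeros((n, n))
    seen = np.zeros(n, dtype=bool)
    for partition in stages:
        for group in partition:
            idx = np.asarray(group, dtype=int)
            if np.any(idx < 0) or np.any(idx >= n):
                raise ValueError("record references samples outside 0..n-1")
            seen[idx] = True
            S[np.ix_(idx, idx)] += 1.0
    if not seen.all():
        missing = int(np.flatnonzero(~seen)[0])
        raise ValueError(f"record does not cover sample {missing}")
    S /= len(stages)
    np.fill_diagonal(S, 1.0)
    return S


def pooled_similarity(records: Sequence[GroupingRecord], n: int) -> np.ndarray:
    """Subject-averaged co-grouping similarity matrix (n × n, entries in [0,1])."""
    if not records:
        raise ValueError("no grouping records")
    S = np.zeros((n, n))
    for rec in records:
        S += _subject_similarity(rec, n)
    S /= len(records)
    np.fill_diagonal(S, 1.0)
    return S


def model_similarity(S: np.ndarray, labels: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Model-level block average of the sample similarity matrix.

    Returns ``(S_mod, models)`` where ``models`` lists model ids in order of
    first appearance. Within-model blocks exclude the diagonal, which would
    otherwise inflate self-similarity.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if len(labels) != n:
        raise ValueError("labels length must match similarity matrix size")
    models = unique_models(labels)
    lab = np.asarray(labels, dtype=object)
    idx = {m: np.flatnonzero(lab == m) for m in models}
    m = len(models)
    out = np.zeros((m, m))
    for a, ma in enumerate(models):
        for b, mb in enumerate(models):
            block = S[np.ix_(idx[ma], idx[mb])]
            if a == b:
                k = block.shape[0]
                if k < 2:
                    raise ValueError(
                        f"model {ma} has < 2 samples; within-model mean undefined")
                out[a, b] = (block.sum() - np.trace(block)) / (k * k - k)
            else:
                out[a, b] = block.mean()
    return out, models


def sample_feature_matrix(ratings: np.ndarray) -> np.ndarray:
    """Average the rating tensor (subjects × samples × 12) over raters.

    NaN entries mark samples a subject did not rate; each matrix entry
    averages exactly its available raters. A sample rated by nobody is an
    error.
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 3 or R.shape[2] != len(FEATURE_NAMES):
        raise ValueError(f"ratings must be subjects × samples × {len(FEATURE_NAMES)}")
    if R.shape[0] < 1:
        raise ValueError("need at least one subject")
    counts = np.sum(~np.isnan(R), axis=0)
    if np.any(counts == 0):
        i = int(np.argwhere(counts == 0)[0][0])
        raise ValueError(f"sample {i} was rated by nobody")
    with np.errstate(invalid="ignore"):
        return np.nansum(R, axis=0) / counts


def model_feature_matrix(F_tex: np.ndarray,
                         labels: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Per-model average of sample feature rows; returns ``(F_mod, models)``."""
    F = np.asarray(F_tex, dtype=float)
    if F.shape[0] != len(labels):
        raise ValueError("labels length must match feature matrix rows")
    models = unique_models(labels)
    lab = np.asarray(labels, dtype=object)
    rows = [F[lab == m].mean(axis=0) for m in models]
    return np.vstack(rows), models
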