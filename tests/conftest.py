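import warnings

import numpy as np
import pytest

import texspace as tx
from texspace.workbench import PipelineConfig, run_full_pipeline


@pytest.fixture(scope="session")
def manifest200():
    """Default-scale dataset manifest (200 textures, no pixel synthesis)."""
    return tx.build_dataset(tx.scaled_counts(200), with_heights=False)


class _PipelineCache:
    """Lazily computed default-pipeline runs, shared across the session."""

    def __init__(self):
        self._runs = {}

    def __call__(self, seed: int):
        if seed not in self._runs:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result, _ = run_full_pipeline(PipelineConfig(master_seed=seed))
            self._runs[seed] = result
        return self._runs[seed]


@pytest.fixture(scope="session")
def default_run():
    """Callable seed -> PipelineResult for the default synthetic study."""
    return _PipelineCache()


@pytest.fixture(scope="session")
def tiny_counts():
    return {"perlin_noise": 4, "cellular": 4, "texton_regular": 4,
            "matrix_transformation": 4, "wavelet_noise": 4}


@pytest.fixture(scope="session")
def tiny_config(tiny_counts):
    """A fast five-model configuration for orchestration tests."""
    return PipelineConfig(counts=dict(tiny_counts), size=96, master_seed=7,
                          n_grouping_subjects=6, n_rating_subjects=8,
                          k_neighbors=6, cv_folds=3, with_heights=True,
                          render_images=True)


@pytest.fixture(scope="session")
def tiny_run(tiny_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result, report = run_full_pipeline(tiny_config)
    return result, report


def random_dissimilarity(rng: np.random.Generator, n: int,
                         dim: int = 5) -> np.ndarray:
    """Euclidean dissimilarity matrix of random points (valid metric)."""
    pts = rng.normal(size=(n, dim))
    diff = pts[:, None] - pts[None]
    D = np.sqrt((diff ** 2).sum(-1))
    return D / D.max()
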