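"""Registry of procedural height-map generators and dataset assembly.

Twenty-three texture model families are registered, spanning three broad
perceptual regimes: regular/structured patterns (weave gratings, star
ornaments, regular texton grids), granular random fields (noises, fractal
spectra, distance fields, forest-fire automata) and near-regular random
patterns (jittered/walked textons, excitable media, reaction–diffusion).
Each model declares one or two sweepable parameters with closed ranges;
parameter sweeps move all swept parameters together along evenly spaced
values ("linearly increasing" the parameters), and every sample gets a
deterministic seed derived from the master seed, the model id and the sweep
index.

Height maps are min–max normalized to [0, 1]; a degenerate constant field
maps to all 0.5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from . import _generators as G
from ._seeds import child_seed

__all__ = [
    "ParamSet",
    "HeightMap",
    "TextureDataset",
    "ModelSpec",
    "MODEL_REGISTRY",
    "model_ids",
    "generate_height_map",
    "parameter_sweep",
    "build_dataset",
    "full_default_counts",
    "scaled_counts",
    "export_height_map",
]


# ---------------------------------------------------------------------------
# types

@dataclass(frozen=True)
class ParamSet:
    """One point in a model's parameter space plus its sample seed."""

    model_id: str
    values: Mapping[str, float]
    seed: int

    def __post_init__(self):
        spec = get_model(self.model_id)
        for name, val in self.values.items():
            if name not in spec.params:
                raise ValueError(f"{self.model_id}: unknown parameter {name!r}")
            lo, hi = spec.params[name]
            if not (lo <= val <= hi):
                raise ValueError(
                    f"{self.model_id}: parameter {name}={val} outside [{lo}, {hi}]")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclass(frozen=True)
class HeightMap:
    """Normalized square surface-height grid with its provenance."""

    heights: np.ndarray
    provenance: ParamSet

    @property
    def size(self) -> int:
        return self.heights.shape[0]


@dataclass
class TextureDataset:
    """Ordered texture samples with per-sample model labels and parameters.

    ``samples`` may be None when only the manifest (labels, parameters,
    sweep positions) is needed, e.g. to drive the synthetic observer without
    paying for pixel synthesis.
    """

    labels: list[str]
    manifest: list[ParamSet]
    sweep_positions: np.ndarray  # normalized sweep position in [0,1] per sample
    samples: list[HeightMap] | None = None
    size: int = 512

    def __len__(self) -> int:
        return len(self.labels)

    def height_map(self, i: int) -> HeightMap:
        if self.samples is not None:
            return self.samples[i]
        return generate_height_map(self.manifest[i], self.size)


# ---------------------------------------------------------------------------
# registry

@dataclass(frozen=True)
class ModelSpec:
    model_id: str
    generator: Callable[..., np.ndarray]
    params: Mapping[str, tuple[float, float]]  # name -> (low, high)
    integer_params: frozenset[str] = frozenset()
    full_count: int = 20  # samples contributed to the 450-sample default set
    min_size: Callable[[Mapping[str, float]], int] | None = None


def _texton_grid(rng, size, spacing=32, radius_frac=0.3, jitter=0.0):
    sp = max(4, int(round(spacing)))
    pos = np.array([(y, x) for y in range(0, size, sp) for x in range(0, size, sp)],
                   dtype=float)
    pos += rng.uniform(0, sp, size=2)  # random global phase
    if jitter > 0:
        pos += rng.uniform(-jitter * sp, jitter * sp, size=pos.shape)
    return G.texton_field(rng, size, pos, radius_frac * sp)


def _gen_texton_regular(rng, size, spacing=32, radius_frac=0.3):
    return _texton_grid(rng, size, spacing, radius_frac, jitter=0.0)


def _gen_texton_random_grid(rng, size, spacing=32, jitter=0.3):
    return _texton_grid(rng, size, spacing, 0.3, jitter=jitter)


def _gen_texton_random_walk(rng, size, n_steps=300, step=16):
    pos = G.random_walk_positions(rng, size, max(10, int(round(n_steps))), step)
    return G.texton_field(rng, size, pos, 0.35 * step)


def _gen_texton_probability_map(rng, size, n_textons=250, map_scale=2.0):
    pmap = G.spectral_synthesis(rng, size, beta=map_scale)
    pmap = pmap - pmap.min()
    p = (pmap / pmap.sum()).ravel()
    n = max(10, int(round(n_textons)))
    flat = rng.choice(size * size, size=n, replace=True, p=p)
    pos = np.stack(np.unravel_index(flat, (size, size)), axis=1)
    return G.texton_field(rng, size, pos, max(2.0, size / 64.0))


def _gen_texton_addition(rng, size, n_textons=200, radius_frac=0.04):
    n = max(10, int(round(n_textons)))
    pos = rng.uniform(0, size, size=(n, 2))
    return G.texton_field(rng, size, pos, max(1.5, radius_frac * size),
                          additive=True)


def _fold(base: np.ndarray, folds: float) -> np.ndarray:
    return G.triangle_fold(base, int(round(folds)))


def _gen_folding_perlin(rng, size, frequency=6.0, folds=2):
    return _fold(G.perlin(rng, size, frequency), folds)


def _gen_folding_cellular(rng, size, n_points=24, folds=2):
    return _fold(G.cellular(rng, size, n_points), folds)


def _gen_folding_fractal(rng, size, beta=1.8, folds=2):
    return _fold(G.spectral_synthesis(rng, size, beta), folds)


def _gen_folding_texton(rng, size, spacing=32, folds=2):
    return _fold(_gen_texton_random_grid(rng, size, spacing, 0.3), folds)


def _norm01(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    return (a - lo) / (hi - lo) if hi > lo else np.full_like(a, 0.5)


def _gen_fusion(gen_a, gen_b):
    def fuse(rng, size, weight=0.5, detail=1.0):
        a = _norm01(gen_a(rng, size, detail))
        b = _norm01(gen_b(rng, size, detail))
        return weight * a + (1.0 - weight) * b
    return fuse


def _component_perlin(rng, size, detail):
    return G.perlin(rng, size, frequency=4.0 + 8.0 * detail)


def _component_cellular(rng, size, detail):
    return G.cellular(rng, size, n_points=12 + 36 * detail)


def _component_texton(rng, size, detail):
    return _gen_texton_random_grid(rng, size, spacing=48 - 24 * detail, jitter=0.3)


def _texton_min_size(params: Mapping[str, float]) -> int:
    return int(round(params.get("spacing", 32))) + 1


_R: dict[str, ModelSpec] = {}


def _register(spec: ModelSpec) -> None:
    _R[spec.model_id] = spec


# registry order fixes dataset sample order; numbering follows the standard
# alphabetical family listing (CA models first, wavelet noise last)
_register(ModelSpec("ca_forest_fire", G.ca_forest_fire,
                    {"growth": (0.01, 0.08), "f_ratio": (50.0, 200.0)},
                    full_count=20))
_register(ModelSpec("ca_surface_tension", G.ca_surface_tension,
                    {"density": (0.35, 0.65), "iterations": (2, 16)},
                    integer_params=frozenset({"iterations"}), full_count=15))
_register(ModelSpec("ca_excitable_media", G.ca_excitable_media,
                    {"n_states": (3, 8), "threshold": (1, 3)},
                    integer_params=frozenset({"n_states", "threshold"}),
                    full_count=15))
_register(ModelSpec("cellular", G.cellular,
                    {"n_points": (8, 64), "variant": (0.0, 1.0)},
                    integer_params=frozenset({"n_points"}), full_count=30))
_register(ModelSpec("folding_texton", _gen_folding_texton,
                    {"spacing": (16, 48), "folds": (1, 3)},
                    integer_params=frozenset({"spacing", "folds"}),
                    full_count=15, min_size=_texton_min_size))
_register(ModelSpec("folding_cellular", _gen_folding_cellular,
                    {"n_points": (8, 48), "folds": (1, 3)},
                    integer_params=frozenset({"n_points", "folds"}),
                    full_count=15))
_register(ModelSpec("folding_fractal", _gen_folding_fractal,
                    {"beta": (1.0, 2.5), "folds": (1, 3)},
                    integer_params=frozenset({"folds"}), full_count=15))
_register(ModelSpec("folding_perlin", _gen_folding_perlin,
                    {"frequency": (2, 12), "folds": (1, 3)},
                    integer_params=frozenset({"folds"}), full_count=15))
_register(ModelSpec("fractal_one_over_f", G.anisotropic_spectral,
                    {"beta": (1.0, 3.0), "anisotropy": (2.0, 8.0)},
                    full_count=20))
_register(ModelSpec("fractal_fourier", G.spectral_synthesis,
                    {"beta": (0.5, 3.0)}, full_count=30))
_register(ModelSpec("fusion_cellular_texton",
                    _gen_fusion(_component_cellular, _component_texton),
                    {"weight": (0.2, 0.8), "detail": (0.0, 1.0)}, full_count=20))
_register(ModelSpec("fusion_perlin_cellular",
                    _gen_fusion(_component_perlin, _component_cellular),
                    {"weight": (0.2, 0.8), "detail": (0.0, 1.0)}, full_count=20))
_register(ModelSpec("fusion_perlin_texton",
                    _gen_fusion(_component_perlin, _component_texton),
                    {"weight": (0.2, 0.8), "detail": (0.0, 1.0)}, full_count=15))
_register(ModelSpec("islamic_patterns", G.islamic_pattern,
                    {"n_fold": (4, 9), "cells": (2, 5)},
                    integer_params=frozenset({"n_fold", "cells"}), full_count=15))
_register(ModelSpec("matrix_transformation", G.matrix_transformation,
                    {"frequency": (4, 16), "contrast": (0.3, 0.9)},
                    integer_params=frozenset({"frequency"}), full_count=15))
_register(ModelSpec("perlin_noise", G.perlin,
                    {"frequency": (2, 16)}, full_count=30))
_register(ModelSpec("reaction_diffusion", G.gray_scott,
                    {"feed": (0.030, 0.044), "kill": (0.057, 0.063)},
                    full_count=20))
_register(ModelSpec("texton_addition", _gen_texton_addition,
                    {"n_textons": (50, 400), "radius_frac": (0.02, 0.08)},
                    integer_params=frozenset({"n_textons"}), full_count=20))
_register(ModelSpec("texton_probability_map", _gen_texton_probability_map,
                    {"n_textons": (100, 500), "map_scale": (1.5, 2.5)},
                    integer_params=frozenset({"n_textons"}), full_count=20))
_register(ModelSpec("texton_random_grid", _gen_texton_random_grid,
                    {"spacing": (16, 64), "jitter": (0.1, 0.5)},
                    integer_params=frozenset({"spacing"}), full_count=20,
                    min_size=_texton_min_size))
_register(ModelSpec("texton_random_walk", _gen_texton_random_walk,
                    {"n_steps": (100, 600), "step": (8, 32)},
                    integer_params=frozenset({"n_steps"}), full_count=20))
_register(ModelSpec("texton_regular", _gen_texton_regular,
                    {"spacing": (16, 64), "radius_frac": (0.15, 0.45)},
                    integer_params=frozenset({"spacing"}), full_count=25,
                    min_size=_texton_min_size))
_register(ModelSpec("wavelet_noise", G.wavelet_noise,
                    {"scale": (1.0, 4.0)}, full_count=20))

MODEL_REGISTRY: Mapping[str, ModelSpec] = _R


def model_ids() -> list[str]:
    """Registered model identifiers in registry (dataset) order."""
    return list(MODEL_REGISTRY)


def get_model(model_id: str) -> ModelSpec:
    try:
        return MODEL_REGISTRY[model_id]
    except KeyError:
        raise ValueError(f"unknown model_id {model_id!r}") from None


def full_default_counts() -> dict[str, int]:
    """Per-model sample counts of the full 450-sample default configuration."""
    return {m: s.full_count for m, s in MODEL_REGISTRY.items()}


def scaled_counts(total: int, min_per_model: int = 2) -> dict[str, int]:
    """Scale the full configuration proportionally to ``total`` samples.

    Uses largest-remainder apportionment with a floor of ``min_per_model``
    samples per model so every family stays represented.
    """
    full = full_default_counts()
    grand = sum(full.values())
    raw = {m: total * c / grand for m, c in full.items()}
    counts = {m: max(min_per_model, int(np.floor(v))) for m, v in raw.items()}
    leftover = total - sum(counts.values())
    order = sorted(full, key=lambda m: raw[m] - np.floor(raw[m]), reverse=True)
    i = 0
    while leftover != 0 and i < 10 * len(order):
        m = order[i % len(order)]
        if leftover > 0:
            counts[m] += 1
            leftover -= 1
        elif counts[m] > min_per_model:
            counts[m] -= 1
            leftover += 1
        i += 1
    return counts


# ---------------------------------------------------------------------------
# operations

def generate_height_map(params: ParamSet, size: int = 512) -> HeightMap:
    """Synthesize one normalized height map; deterministic in (params, size)."""
    if size < 16:
        raise ValueError("size must be >= 16")
    spec = get_model(params.model_id)
    if spec.min_size is not None and size < spec.min_size(params.values):
        raise ValueError(
            f"{params.model_id}: size {size} too small for structural scale "
            f"(needs >= {spec.min_size(params.values)})")
    rng = np.random.default_rng(params.seed)
    kwargs = dict(params.values)
    for name in spec.integer_params:
        if name in kwargs:
            kwargs[name] = int(round(kwargs[name]))
    field = spec.generator(rng, size, **kwargs)
    field = np.asarray(field, dtype=np.float64)
    if not np.all(np.isfinite(field)):
        raise RuntimeError(f"{params.model_id}: non-finite values generated")
    return HeightMap(_norm01(field), params)


def parameter_sweep(model_id: str, n: int, master_seed: int = 0) -> list[ParamSet]:
    """Evenly spaced joint sweep of all declared parameters.

    Each swept parameter takes ``n`` evenly spaced values including both
    range endpoints (``n == 1`` uses the midpoint); values are paired across
    parameters so the sweep moves along a line in parameter space. Seeds are
    derived from ``master_seed``, the model id and the sweep index.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = get_model(model_id)
    out = []
    for i in range(n):
        frac = 0.5 if n == 1 else i / (n - 1)
        values = {}
        for name, (lo, hi) in spec.params.items():
            v = min(max(lo + frac * (hi - lo), lo), hi)
            if name in spec.integer_params:
                v = float(int(round(v)))
            values[name] = v
        out.append(ParamSet(model_id, values,
                            child_seed(master_seed, model_id, i)))
    return out


def build_dataset(per_model_counts: Mapping[str, int], size: int = 512,
                  master_seed: int = 0, with_heights: bool = True) -> TextureDataset:
    """Assemble a dataset: registry order across models, sweep order within.

    With ``with_heights=False`` only the manifest is materialized; maps can
    be synthesized on demand via :meth:`TextureDataset.height_map`.
    """
    if not per_model_counts:
        raise ValueError("empty dataset configuration")
    for m in per_model_counts:
        get_model(m)
    if len(per_model_counts) < 2:
        raise ValueError("at least 2 models required")
    labels: list[str] = []
    manifest: list[ParamSet] = []
    positions: list[float] = []
    for model_id in model_ids():
        if model_id not in per_model_counts:
            continue
        n = int(per_model_counts[model_id])
        if n < 1:
            raise ValueError(f"count for {model_id} must be >= 1")
        if n < 2:
            warnings.warn(f"model {model_id} has only {n} sample", stacklevel=2)
        for i, ps in enumerate(parameter_sweep(model_id, n, master_seed)):
            labels.append(model_id)
            manifest.append(ps)
            positions.append(0.5 if n == 1 else i / (n - 1))
    samples = None
    if with_heights:
        samples = [generate_height_map(ps, size) for ps in manifest]
    return TextureDataset(labels=labels, manifest=manifest,
                          sweep_positions=np.asarray(positions),
                          samples=samples, size=size)


# ---------------------------------------------------------------------------
# export

def export_height_map(hm: HeightMap, path: str | Path) -> None:
    """Write a height map as 16-bit grayscale PNG or plain-text PGM (P2).

    The format follows the file suffix (.png or .pgm).
    """
    path = Path(path)
    q = np.round(hm.heights * 65535.0).astype(np.uint16)
    if path.suffix.lower() == ".png":
        from PIL import Image
        Image.fromarray(q).save(path)
    elif path.suffix.lower() == ".pgm":
        lines = [f"P2\n{q.shape[1]} {q.shape[0]}\n65535\n"]
        for row in q:
            lines.append(" ".join(str(v) for v in row) + "\n")
        path.write_text("".join(lines))
    else:
        raise ValueError(f"unsupported height-map format: {path.suffix}")


def write_manifest(dataset: TextureDataset, path: str | Path) -> None:
    """Write the per-sample manifest (model, parameters, seed) as JSON."""
    records = [
        {"index": i, "model_id": ps.model_id, "parameters": dict(ps.values),
         "seed": ps.seed}
        for i, ps in enumerate(dataset.manifest)
    ]
    Path(path).write_text(json.dumps(records, indent=1))
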