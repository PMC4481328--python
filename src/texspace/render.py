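"""Lambertian shading of height maps under slant/tilt illumination.

The illumination geometry follows the convention common in shape-from-shading
work: the light direction is ``l = (sin σ cos τ, sin σ sin τ, cos σ)`` with
slant σ (zenith angle) and tilt τ (azimuth, measured from the +x axis).
Image intensity is ``I = albedo · max(0, n·l)`` per pixel, a local-shading
model with attached shadows but no cast shadows or inter-reflections; the
downstream analysis consumes images only through the synthetic observer, so
global illumination is not load-bearing here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .texgen import HeightMap

__all__ = ["LightConfig", "RenderedImage", "surface_normals",
           "render_lambertian", "export_image"]


@dataclass(frozen=True)
class LightConfig:
    """Illumination and surface-scale parameters.

    slant/tilt in degrees; ``height_scale`` converts normalized height units
    to pixel spacing before differentiation (the physical relief amplitude
    relative to the pixel grid).
    """

    slant: float = 45.0
    tilt: float = 135.0
    albedo: float = 1.0
    height_scale: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.slant < 90.0):
            raise ValueError("slant must be in [0, 90)")
        if not (0.0 <= self.tilt < 360.0):
            raise ValueError("tilt must be in [0, 360)")
        if not (0.0 < self.albedo <= 1.0):
            raise ValueError("albedo must be in (0, 1]")
        if self.height_scale <= 0:
            raise ValueError("height_scale must be positive")

    @property
    def direction(self) -> np.ndarray:
        s, t = np.radians(self.slant), np.radians(self.tilt)
        return np.array([np.sin(s) * np.cos(t), np.sin(s) * np.sin(t), np.cos(s)])


@dataclass(frozen=True)
class RenderedImage:
    """Shaded intensities in [0, 1], same grid as the source height map."""

    intensities: np.ndarray


def surface_normals(hm: HeightMap | np.ndarray,
                    height_scale: float = 1.0) -> np.ndarray:
    """Unit surface normals from central differences.

    Returns an (n, n, 3) array of ``normalize(-h_x·s, -h_y·s, 1)`` where the
    x axis runs along columns and y along rows; borders use replicated edges
    (gradient of the edge-padded field).
    """
    h = hm.heights if isinstance(hm, HeightMap) else np.asarray(hm, dtype=float)
    padded = np.pad(h, 1, mode="edge")
    hy = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    hx = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    n = np.stack([-hx * height_scale, -hy * height_scale, np.ones_like(h)], axis=-1)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    return n


def render_lambertian(hm: HeightMap | np.ndarray,
                      light: LightConfig = LightConfig()) -> RenderedImage:
    """Shade a height map: ``I = albedo · max(0, n·l)``, clamped to [0, 1]."""
    normals = surface_normals(hm, light.height_scale)
    intensity = light.albedo * np.einsum("ijk,k->ij", normals, light.direction)
    return RenderedImage(np.clip(intensity, 0.0, 1.0))


def export_image(img: RenderedImage, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG; pixel = round(255 · intensity)."""
    from PIL import Image
    q = np.round(img.intensities * 255.0).astype(np.uint8)
    Image.fromarray(q, mode="L").save(Path(path))
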