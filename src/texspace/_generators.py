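"""Procedural height-field synthesis primitives.

Each generator takes a ``numpy.random.Generator`` and an image side length
and returns a raw (unnormalized) float field; :mod:`texspace.texgen`
normalizes to [0, 1] and owns the public registry. All fields are synthesized
on a torus: noise lattices tile, texton stamps wrap, and cellular-automaton
neighborhoods are periodic, so no generator produces border artifacts.

The cellular automata expose their single-step update rules
(:func:`forest_fire_step`, :func:`surface_tension_step`,
:func:`greenberg_hastings_step`) so the state alphabet can be inspected at
every step of a simulation, not just in the final field.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "perlin",
    "wavelet_noise",
    "spectral_synthesis",
    "anisotropic_spectral",
    "cellular",
    "forest_fire_step",
    "ca_forest_fire",
    "surface_tension_step",
    "ca_surface_tension",
    "greenberg_hastings_step",
    "ca_excitable_media",
    "gray_scott",
    "matrix_transformation",
    "islamic_pattern",
    "texton_field",
    "random_walk_positions",
    "triangle_fold",
]


# ---------------------------------------------------------------------------
# lattice / spectral noise

def _fade(t: np.ndarray) -> np.ndarray:
    # quintic fade 6t^5 - 15t^4 + 10t^3: C2-continuous at lattice points
    return t * t * t * (t * (t * 6.0 - 15.0) + 10.0)


def perlin(rng: np.random.Generator, size: int, frequency: float = 8.0) -> np.ndarray:
    """Tileable 2-D gradient (Perlin) noise with ``frequency`` lattice cells."""
    f = max(1, int(round(frequency)))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(f, f))
    gx, gy = np.cos(theta), np.sin(theta)

    coords = np.arange(size, dtype=np.float64) * (f / size)
    cy, cx = np.meshgrid(coords, coords, indexing="ij")
    iy, ix = np.floor(cy).astype(int), np.floor(cx).astype(int)
    fy, fx = cy - iy, cx - ix
    iy %= f
    ix %= f
    iy1, ix1 = (iy + 1) % f, (ix + 1) % f

    def dot(iyc, ixc, offy, offx):
        return gy[iyc, ixc] * (fy - offy) + gx[iyc, ixc] * (fx - offx)

    n00 = dot(iy, ix, 0.0, 0.0)
    n01 = dot(iy, ix1, 0.0, 1.0)
    n10 = dot(iy1, ix, 1.0, 0.0)
    n11 = dot(iy1, ix1, 1.0, 1.0)

    uy, ux = _fade(fy), _fade(fx)
    top = n00 + ux * (n01 - n00)
    bot = n10 + ux * (n11 - n10)
    return top + uy * (bot - top)


def _freq_radius(size: int) -> np.ndarray:
    f = np.fft.fftfreq(size) * size  # cycles per image
    fy, fx = np.meshgrid(f, f, indexing="ij")
    return np.hypot(fy, fx), fy, fx


def wavelet_noise(rng: np.random.Generator, size: int, scale: float = 2.5,
                  bands: int = 3) -> np.ndarray:
    """Band-limited noise summed over octave-spaced frequency bands.

    ``scale`` sets the base band center at ``2**scale`` cycles per image;
    successive bands double the center frequency with geometrically
    decreasing weight.
    """
    r, _, _ = _freq_radius(size)
    white = np.fft.fft2(rng.standard_normal((size, size)))
    out = np.zeros((size, size))
    for b in range(bands):
        fc = 2.0 ** (scale + b)
        if fc >= size / 2:
            break
        mask = np.exp(-(((r - fc) / (0.35 * fc + 1e-9)) ** 2))
        out += (0.55 ** b) * np.real(np.fft.ifft2(white * mask))
    return out


def spectral_synthesis(rng: np.random.Generator, size: int,
                       beta: float = 1.8) -> np.ndarray:
    """Fractal field by random-phase Fourier synthesis, amplitude ∝ 1/f^beta."""
    r, _, _ = _freq_radius(size)
    amp = np.zeros_like(r)
    nz = r > 0
    amp[nz] = r[nz] ** (-beta)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=r.shape)
    return np.real(np.fft.ifft2(amp * np.exp(1j * phase)))


def anisotropic_spectral(rng: np.random.Generator, size: int,
                         beta: float = 2.0, anisotropy: float = 4.0) -> np.ndarray:
    """1/f^beta synthesis with an axis-stretched spectrum.

    ``anisotropy`` > 1 concentrates power near the fy = 0 line, producing
    vertically striped fields (intensity varying mainly across x).
    """
    _, fy, fx = _freq_radius(size)
    r = np.hypot(fx / anisotropy, fy * anisotropy)
    amp = np.zeros_like(r)
    nz = r > 0
    amp[nz] = r[nz] ** (-beta)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=r.shape)
    return np.real(np.fft.ifft2(amp * np.exp(1j * phase)))


# ---------------------------------------------------------------------------
# cellular (Worley) distance fields

def cellular(rng: np.random.Generator, size: int, n_points: float = 24,
             variant: float = 0.0) -> np.ndarray:
    """Nearest-feature-point distance field on a torus.

    ``variant`` < 0.5 returns F1 (distance to nearest point), otherwise
    F2 - F1. Distances use the wrap-around metric.
    """
    n = max(2, int(round(n_points)))
    pts = rng.uniform(0.0, size, size=(n, 2))
    yy, xx = np.meshgrid(np.arange(size, dtype=np.float64),
                         np.arange(size, dtype=np.float64), indexing="ij")
    d1 = np.full((size, size), np.inf)
    d2 = np.full((size, size), np.inf)
    for py, px in pts:
        dy = np.abs(yy - py)
        dx = np.abs(xx - px)
        dy = np.minimum(dy, size - dy)
        dx = np.minimum(dx, size - dx)
        d = np.hypot(dy, dx)
        closer = d < d1
        d2 = np.where(closer, d1, np.minimum(d2, d))
        d1 = np.where(closer, d, d1)
    return (d2 - d1) if variant >= 0.5 else d1


# ---------------------------------------------------------------------------
# cellular automata (toroidal neighborhoods)

EMPTY, TREE, BURNING = 0, 1, 2

_ROLLS_4 = ((1, 0), (-1, 0), (0, 1), (0, -1))
_ROLLS_8 = _ROLLS_4 + ((1, 1), (1, -1), (-1, 1), (-1, -1))


def _neighbor_count(mask: np.ndarray, rolls=_ROLLS_8) -> np.ndarray:
    out = np.zeros(mask.shape, dtype=np.int64)
    for dy, dx in rolls:
        out += np.roll(mask, (dy, dx), axis=(0, 1))
    return out


def forest_fire_step(state: np.ndarray, growth: float, ignition: float,
                     rng: np.random.Generator) -> np.ndarray:
    """One Drossel–Schwabl update: burn spreads, trees grow (p), lightning (f)."""
    burning_nb = _neighbor_count(state == BURNING, _ROLLS_4) > 0
    new = np.where(state == BURNING, EMPTY, state)
    tree = state == TREE
    catch = tree & (burning_nb | (rng.random(state.shape) < ignition))
    new = np.where(catch, BURNING, new)
    grow = (state == EMPTY) & (rng.random(state.shape) < growth)
    new = np.where(grow, TREE, new)
    return new.astype(np.int64)


def ca_forest_fire(rng: np.random.Generator, size: int, growth: float = 0.03,
                   f_ratio: float = 100.0, steps: int = 150) -> np.ndarray:
    """Forest-fire automaton; final tree/burn/empty pattern as a height field."""
    state = (rng.random((size, size)) < 0.4).astype(np.int64)  # sparse trees
    ignition = growth / max(f_ratio, 1.0)
    for _ in range(steps):
        state = forest_fire_step(state, growth, ignition, rng)
    heights = np.array([0.0, 1.0, 0.5])
    return heights[state]


def surface_tension_step(state: np.ndarray) -> np.ndarray:
    """Local-majority vote over the 3x3 neighborhood (binary states)."""
    votes = _neighbor_count(state == 1, _ROLLS_8) + (state == 1)
    return (votes >= 5).astype(np.int64)


def ca_surface_tension(rng: np.random.Generator, size: int,
                       density: float = 0.5, iterations: float = 8) -> np.ndarray:
    """Iterated majority smoothing of binary noise: blobby phase domains."""
    state = (rng.random((size, size)) < density).astype(np.int64)
    for _ in range(max(1, int(round(iterations)))):
        state = surface_tension_step(state)
    return state.astype(np.float64)


def greenberg_hastings_step(state: np.ndarray, n_states: int,
                            threshold: int) -> np.ndarray:
    """Greenberg–Hastings excitable medium: rest(0)/excited(1)/refractory(2..)."""
    excited_nb = _neighbor_count(state == 1, _ROLLS_8)
    new = np.where(state > 0, (state + 1) % n_states, 0)
    fire = (state == 0) & (excited_nb >= threshold)
    return np.where(fire, 1, new).astype(np.int64)


def ca_excitable_media(rng: np.random.Generator, size: int, n_states: float = 5,
                       threshold: float = 1, steps: int = 80) -> np.ndarray:
    """Excitable-media automaton; spiral/labyrinth wave fronts."""
    ns = max(3, int(round(n_states)))
    state = rng.integers(0, ns, size=(size, size))
    th = max(1, int(round(threshold)))
    for _ in range(steps):
        state = greenberg_hastings_step(state, ns, th)
        if not np.any(state == 1):  # activity died: re-ignite a random patch
            r = max(2, size // 16)
            cy, cx = rng.integers(0, size, size=2)
            ys = np.arange(cy - r, cy + r) % size
            xs = np.arange(cx - r, cx + r) % size
            state[np.ix_(ys, xs)] = 1
    return state / (ns - 1)


def gray_scott(rng: np.random.Generator, size: int, feed: float = 0.036,
               kill: float = 0.0595, steps: int = 3000,
               du: float = 0.16, dv: float = 0.08) -> np.ndarray:
    """Gray–Scott reaction-diffusion integrated to a quasi-steady pattern."""
    u = np.ones((size, size))
    v = np.zeros((size, size))
    n_seeds = max(4, size // 16)
    r = max(2, size // 32)
    for _ in range(n_seeds):
        cy, cx = rng.integers(0, size, size=2)
        ys = np.arange(cy - r, cy + r) % size
        xs = np.arange(cx - r, cx + r) % size
        v[np.ix_(ys, xs)] = 0.25
        u[np.ix_(ys, xs)] = 0.5
    u += 0.02 * rng.standard_normal((size, size))
    v += 0.02 * np.abs(rng.standard_normal((size, size)))

    def lap(a):
        return (np.roll(a, 1, 0) + np.roll(a, -1, 0) +
                np.roll(a, 1, 1) + np.roll(a, -1, 1) - 4.0 * a)

    for _ in range(steps):
        uvv = u * v * v
        u += du * lap(u) - uvv + feed * (1.0 - u)
        v += dv * lap(v) + uvv - (feed + kill) * v
        np.clip(u, 0.0, 1.5, out=u)
        np.clip(v, 0.0, 1.0, out=v)
    return v


# ---------------------------------------------------------------------------
# structured / ornamental patterns

def matrix_transformation(rng: np.random.Generator, size: int,
                          frequency: float = 8, contrast: float = 0.7) -> np.ndarray:
    """Fabric weave: orthogonal sinusoid gratings interleaved on a checker."""
    f = max(2, int(round(frequency)))
    x = np.arange(size) / size
    gy = np.sin(2.0 * np.pi * f * x)[:, None] * np.ones((1, size))
    gx = np.sin(2.0 * np.pi * f * x)[None, :] * np.ones((size, 1))
    cell = max(1, size // (2 * f))
    yy, xx = np.meshgrid(np.arange(size) // cell, np.arange(size) // cell,
                         indexing="ij")
    checker = (yy + xx) % 2 == 0
    field = np.where(checker, gy, contrast * gx)
    return field + 0.01 * rng.standard_normal((size, size))


def islamic_pattern(rng: np.random.Generator, size: int, n_fold: float = 6,
                    cells: float = 4) -> np.ndarray:
    """A random star motif replicated under a p4m-like wallpaper symmetry."""
    n = max(3, int(round(n_fold)))
    c = max(2, int(round(cells)))
    cell = size // c
    if cell < 8:
        cell = 8
        c = size // cell
    phase = rng.uniform(0.0, 2.0 * np.pi)
    u = (np.arange(cell) + 0.5) / cell * 2.0 - 1.0
    vy, vx = np.meshgrid(u, u, indexing="ij")
    r = np.hypot(vy, vx)
    theta = np.arctan2(vy, vx)
    star = np.clip(np.cos(n * theta + phase), 0.0, 1.0) * np.clip(1.0 - r, 0.0, 1.0)
    star += (r < 0.25) * (0.25 - r) * 2.0
    tile = np.zeros((size, size))
    for i in range(c):
        for j in range(c):
            block = star
            if i % 2 == 1:
                block = block[::-1, :]
            if j % 2 == 1:
                block = block[:, ::-1]
            tile[i * cell:(i + 1) * cell, j * cell:(j + 1) * cell] = block
    rem = size - c * cell
    if rem:  # wrap the partial border so the field stays toroidal
        tile[c * cell:, :] = tile[:rem, :]
        tile[:, c * cell:] = tile[:, :rem]
    return tile


# ---------------------------------------------------------------------------
# texton placement

def _gaussian_stamp(radius: float) -> np.ndarray:
    k = max(3, int(round(radius * 3)))
    u = np.arange(-k, k + 1)
    yy, xx = np.meshgrid(u, u, indexing="ij")
    return np.exp(-(yy ** 2 + xx ** 2) / (2.0 * radius ** 2))


def _paste(canvas: np.ndarray, stamp: np.ndarray, y: int, x: int,
           additive: bool) -> None:
    size = canvas.shape[0]
    k = stamp.shape[0]
    rows = (np.arange(k) + y - k // 2) % size
    cols = (np.arange(k) + x - k // 2) % size
    idx = np.ix_(rows, cols)
    if additive:
        canvas[idx] += stamp
    else:
        canvas[idx] = np.maximum(canvas[idx], stamp)


def texton_field(rng: np.random.Generator, size: int,
                 positions: np.ndarray, radius: float,
                 additive: bool = False) -> np.ndarray:
    """Stamp a Gaussian micro-pattern at the given toroidal positions."""
    stamp = _gaussian_stamp(max(1.0, radius))
    canvas = np.zeros((size, size))
    for y, x in np.asarray(positions, dtype=int):
        _paste(canvas, stamp, int(y) % size, int(x) % size, additive)
    return canvas


def random_walk_positions(rng: np.random.Generator, size: int, n_steps: int,
                          step: float) -> np.ndarray:
    """Positions visited by an isotropic random walk on the torus."""
    angles = rng.uniform(0.0, 2.0 * np.pi, size=n_steps)
    deltas = np.stack([np.sin(angles), np.cos(angles)], axis=1) * step
    pos = np.cumsum(deltas, axis=0) + rng.uniform(0, size, size=2)
    return np.mod(pos, size)


def triangle_fold(field: np.ndarray, folds: int) -> np.ndarray:
    """Iterated triangle fold |2h-1| of a [0,1]-normalized field."""
    lo, hi = field.min(), field.max()
    h = (field - lo) / (hi - lo) if hi > lo else np.full_like(field, 0.5)
    for _ in range(max(1, folds)):
        h = np.abs(2.0 * h - 1.0)
    return h
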