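"""Shared fixtures: digital masks, icospheres, small phantom studies."""

from __future__ import annotations

import numpy as np
import pytest

from livercad.config import Config
from livercad.morphology import SurfaceMesh
from livercad.phantoms import PhantomParams, make_phantom_study
from livercad.study import PHASE_NAMES, TumorStudy


def ball_mask(grid: int = 25, radius: float = 10.0, center=None) -> np.ndarray:
    if center is None:
        center = ((grid - 1) / 2.0,) * 3
    idx = np.indices((grid, grid, grid)).reshape(3, -1).T
    rho = np.linalg.norm(idx - np.asarray(center), axis=1)
    return (rho <= radius).reshape(grid, grid, grid)


def cube_mask(grid: int, side: int) -> np.ndarray:
    m = np.zeros((grid, grid, grid), dtype=bool)
    lo = (grid - side) // 2
    m[lo : lo + side, lo : lo + side, lo : lo + side] = True
    return m


def icosphere(subdivisions: int = 3) -> SurfaceMesh:
    """Unit icosphere built by hand (independent of package mesh code)."""
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, t, 0), (1, t, 0), (-1, -t, 0), (1, -t, 0),
            (0, -1, t), (0, 1, t), (0, -1, -t), (0, 1, -t),
            (t, 0, -1), (t, 0, 1), (-t, 0, -1), (-t, 0, 1),
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = list(map(tuple, verts))
    for _ in range(subdivisions):
        cache = {}
        new_faces = []

        def midpoint(a, b):
            key = tuple(sorted((a, b)))
            if key not in cache:
                p = 0.5 * (np.asarray(verts[a]) + np.asarray(verts[b]))
                p /= np.linalg.norm(p)
                cache[key] = len(verts)
                verts.append(tuple(p))
            return cache[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)]
        faces = new_faces
    return SurfaceMesh(np.array(verts), np.array(faces, dtype=np.intp))


def tiny_study(
    grid: int = 25,
    radius: float = 9.0,
    means=(100.0, 170.0, 155.0, 129.0),
    noise: float = 0.0,
    seed: int = 0,
    grade=None,
) -> TumorStudy:
    """Ball-mask study with exact per-phase means (optionally plus noise)."""
    mask = ball_mask(grid, radius)
    rng = np.random.default_rng(seed)
    phases = {}
    for name, mean in zip(PHASE_NAMES, means):
        vol = np.full((grid, grid, grid), 50.0)
        vol[mask] = mean
        if noise > 0:
            vol = vol + rng.normal(0, noise, vol.shape)
        phases[name] = vol
    return TumorStudy(
        study_id=f"tiny_{seed}", phases=phases, mask=mask, grade=grade
    )


@pytest.fixture(scope="session")
def fast_cfg() -> Config:
    """Small harmonic degree so morphology runs in well under a second."""
    return Config.test_scale(l_max=12, max_iters=30)


@pytest.fixture(scope="session")
def lr3_phantom() -> TumorStudy:
    return make_phantom_study(PhantomParams(grade="LR3", grid=32, base_radius=8, seed=11))


@pytest.fixture(scope="session")
def lr5_phantom() -> TumorStudy:
    return make_phantom_study(PhantomParams(grade="LR5", grid=32, base_radius=8, seed=12))
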