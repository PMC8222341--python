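"""Per-phase first-order and rotation-invariant GLCM / GLRLM texture markers.

All statistics are computed on mask voxels after per-tumor min-max
quantization to 256 gray levels.  The co-occurrence matrix pools the 18
3D offsets of Euclidean length 1 or sqrt(2) (both orders of each pair), and
the run-length matrix pools maximal axis-aligned runs along x, y (in-plane)
and z (through-plane).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
from scipy import stats

from .config import Config
from .errors import (
    EmptyMaskError,
    EmptyRunMatrixError,
    NoCooccurrencesError,
    NotNormalizedError,
)
from .study import PHASE_NAMES, TumorStudy

N_LEVELS = 256

#: nine unique symmetric 3D offsets with length 1 or sqrt(2)
GLCM_OFFSETS = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
)

#: run directions: x and y pooled in-plane, z through-plane
GLRLM_AXES = (0, 1, 2)


@dataclass
class QuantizedRegion:
    """Mask voxels quantized to integer levels 0..255 (-1 outside mask)."""

    levels: np.ndarray  # int16 grid, -1 outside the mask
    mask: np.ndarray  # boolean grid

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def values(self) -> np.ndarray:
        """1D array of levels at mask voxels."""
        return self.levels[self.mask]


@dataclass
class CoocMatrix:
    matrix: np.ndarray  # (256, 256), normalized to sum 1
    n_pairs: int

    def check_normalized(self) -> None:
        if abs(self.matrix.sum() - 1.0) > 1e-8 or np.any(self.matrix < 0):
            raise NotNormalizedError("matrix not normalized")


@dataclass
class RunLengthMatrix:
    matrix: np.ndarray  # (256, R) run counts
    n_voxels: int
    n_directions: int = len(GLRLM_AXES)

    @property
    def n_runs(self) -> int:
        return int(self.matrix.sum())


def normalize_gray_levels(volume: np.ndarray, mask: np.ndarray) -> QuantizedRegion:
    """Affine min-max map of mask-voxel intensities to integers 0..255.

    A constant region maps to all zeros.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise EmptyMaskError("empty mask")
    vals = np.asarray(volume, dtype=float)[mask]
    lo, hi = vals.min(), vals.max()
    levels = np.full(mask.shape, -1, dtype=np.int16)
    if hi == lo:
        levels[mask] = 0
    else:
        scaled = np.rint((vals - lo) / (hi - lo) * (N_LEVELS - 1))
        levels[mask] = scaled.astype(np.int16)
    return QuantizedRegion(levels, mask)


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

FIRST_ORDER_NAMES: List[str] = (
    ["mean", "variance", "std", "skewness", "kurtosis", "entropy"]
    + [f"cdf_{10 * k:03d}" for k in range(1, 11)]
    + [f"pct_{10 * k:03d}" for k in range(1, 11)]
)


def first_order_markers(q: QuantizedRegion) -> Dict[str, float]:
    """26 histogram statistics of the quantized region.

    Six moments/entropy, the normalized-histogram CDF at the ten level
    thresholds k*25.5 (10%..100% of the level range), and the ten gray
    levels at cumulative probabilities 10%..100%.  Zero-variance regions
    report skewness = kurtosis = 0 by convention.
    """
    v = q.values.astype(float)
    hist = np.bincount(q.values, minlength=N_LEVELS).astype(float)
    p = hist / hist.sum()

    mean = float(v.mean())
    var = float(v.var())
    out: Dict[str, float] = {
        "mean": mean,
        "variance": var,
        "std": float(np.sqrt(var)),
        "skewness": float(stats.skew(v)) if var > 0 else 0.0,
        "kurtosis": float(stats.kurtosis(v, fisher=False)) if var > 0 else 0.0,
        "entropy": float(-np.sum(p[p > 0] * np.log2(p[p > 0]))),
    }
    cdf = np.cumsum(p)
    levels = np.arange(N_LEVELS)
    for k in range(1, 11):
        thresh = k * (N_LEVELS - 1) / 10.0
        out[f"cdf_{10 * k:03d}"] = float(cdf[levels <= thresh][-1])
    for k in range(1, 11):
        target = k / 10.0
        idx = int(np.searchsorted(cdf, target - 1e-12))
        out[f"pct_{10 * k:03d}"] = float(min(idx, N_LEVELS - 1))
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def glcm(q: QuantizedRegion) -> CoocMatrix:
    """Pooled symmetric co-occurrence matrix over the 18-neighborhood.

    Counts every ordered voxel pair (both inside the mask) separated by an
    offset of length 1 or sqrt(2); pooling all directions into one matrix
    makes the statistics rotation invariant.
    """
    counts = np.zeros(N_LEVELS * N_LEVELS, dtype=np.int64)
    lv = q.levels
    for off in GLCM_OFFSETS:
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        for ax, o in enumerate(off):
            if o > 0:
                src[ax], dst[ax] = slice(None, -o), slice(o, None)
            elif o < 0:
                src[ax], dst[ax] = slice(-o, None), slice(None, o)
        a = lv[tuple(src)].ravel()
        b = lv[tuple(dst)].ravel()
        keep = (a >= 0) & (b >= 0)
        a, b = a[keep].astype(np.int64), b[keep].astype(np.int64)
        counts += np.bincount(a * N_LEVELS + b, minlength=counts.size)
        counts += np.bincount(b * N_LEVELS + a, minlength=counts.size)
    total = counts.sum()
    if total == 0:
        raise NoCooccurrencesError("no co-occurrences")
    mat = counts.reshape(N_LEVELS, N_LEVELS) / total
    return CoocMatrix(mat, n_pairs=int(total))


GLCM_NAMES: List[str] = [
    "contrast",
    "dissimilarity",
    "homogeneity",
    "asm",
    "energy",
    "correlation",
]


def glcm_markers(cm: CoocMatrix) -> Dict[str, float]:
    """Six Haralick statistics of a normalized co-occurrence matrix."""
    cm.check_normalized()
    p = cm.matrix
    i = np.arange(N_LEVELS)[:, None]
    j = np.arange(N_LEVELS)[None, :]
    diff = i - j
    asm = float(np.sum(p * p))
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    var_i = float(np.sum((i - mu_i) ** 2 * p))
    var_j = float(np.sum((j - mu_j) ** 2 * p))
    if var_i > 0 and var_j > 0:
        corr = float(np.sum((i - mu_i) * (j - mu_j) * p) / np.sqrt(var_i * var_j))
    else:
        corr = 1.0
    return {
        "contrast": float(np.sum(p * diff**2)),
        "dissimilarity": float(np.sum(p * np.abs(diff))),
        "homogeneity": float(np.sum(p / (1.0 + diff**2))),
        "asm": asm,
        "energy": float(np.sqrt(asm)),
        "correlation": corr,
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def _runs_along_axis(levels: np.ndarray, axis: int):
    """(level, length) arrays for maximal constant runs of mask voxels."""
    rows = np.moveaxis(levels, axis, -1).reshape(-1, levels.shape[axis])
    # sentinel column breaks runs at line boundaries
    flat = np.concatenate(
        [rows, np.full((rows.shape[0], 1), -1, dtype=rows.dtype)], axis=1
    ).ravel()
    change = np.flatnonzero(np.diff(flat) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(flat)]])
    vals = flat[starts]
    keep = vals >= 0
    return vals[keep], (ends - starts)[keep]


def glrlm(q: QuantizedRegion) -> RunLengthMatrix:
    """Run-length matrix pooled over the x, y and z directions.

    256 rows (gray levels); column count equals the largest mask
    bounding-box dimension; runs break at mask boundaries or level changes.
    """
    idx = np.nonzero(q.mask)
    r_max = int(max(c.max() - c.min() + 1 for c in idx))
    mat = np.zeros((N_LEVELS, r_max), dtype=np.int64)
    for ax in GLRLM_AXES:
        vals, lengths = _runs_along_axis(q.levels, ax)
        np.add.at(mat, (vals.astype(np.int64), lengths.astype(np.int64) - 1), 1)
    return RunLengthMatrix(mat, n_voxels=q.n_voxels)


GLRLM_NAMES: List[str] = [
    "gln",
    "hglre",
    "lre",
    "lrhgle",
    "lrlgle",
    "lglre",
    "re",
    "rln",
    "rp",
    "sre",
    "srhgle",
    "srlgle",
]


def glrlm_markers(m: RunLengthMatrix) -> Dict[str, float]:
    """Twelve standard run-length statistics on the pooled matrix.

    Gray-level weights use 1-based levels (level g weighs g+1) so the
    low-gray-level emphases are defined at level 0; run percentage is
    normalized by directions * voxels and therefore lies in (0, 1].
    """
    mat = m.matrix.astype(float)
    n_runs = mat.sum()
    if n_runs == 0:
        raise EmptyRunMatrixError("empty run matrix")
    g = (np.arange(N_LEVELS, dtype=float) + 1.0)[:, None]  # 1-based level weight
    l = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]
    row = mat.sum(axis=1)
    col = mat.sum(axis=0)
    p = mat / n_runs
    pnz = p[p > 0]
    return {
        "gln": float(np.sum(row**2) / n_runs),
        "hglre": float(np.sum(mat * g**2) / n_runs),
        "lre": float(np.sum(mat * l**2) / n_runs),
        "lrhgle": float(np.sum(mat * g**2 * l**2) / n_runs),
        "lrlgle": float(np.sum(mat * l**2 / g**2) / n_runs),
        "lglre": float(np.sum(mat / g**2) / n_runs),
        "re": float(-np.sum(pnz * np.log2(pnz))),
        "rln": float(np.sum(col**2) / n_runs),
        "rp": float(n_runs / (m.n_directions * m.n_voxels)),
        "sre": float(np.sum(mat / l**2) / n_runs),
        "srhgle": float(np.sum(mat * g**2 / l**2) / n_runs),
        "srlgle": float(np.sum(mat / (g**2 * l**2)) / n_runs),
    }


# ---------------------------------------------------------------------------
# per-study driver
# ---------------------------------------------------------------------------

PHASE_PREFIXES = {name: name for name in PHASE_NAMES}


def textural_marker_names() -> List[str]:
    names = []
    for phase in PHASE_NAMES:
        names += [f"{phase}_fo_{n}" for n in FIRST_ORDER_NAMES]
        names += [f"{phase}_glcm_{n}" for n in GLCM_NAMES]
        names += [f"{phase}_glrlm_{n}" for n in GLRLM_NAMES]
    return names


def textural_markers(study: TumorStudy, cfg: Optional[Config] = None) -> Dict[str, float]:
    """176 markers: (26 first-order + 6 GLCM + 12 GLRLM) per phase."""
    out: Dict[str, float] = {}
    for phase in PHASE_NAMES:
        q = normalize_gray_levels(study.phases[phase], study.mask)
        for n, v in first_order_markers(q).items():
            out[f"{phase}_fo_{n}"] = v
        for n, v in glcm_markers(glcm(q)).items():
            out[f"{phase}_glcm_{n}"] = v
        for n, v in glrlm_markers(glrlm(q)).items():
            out[f"{phase}_glrlm_{n}"] = v
    return out
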