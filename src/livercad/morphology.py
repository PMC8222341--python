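"""Shape markers from spherical-harmonic surface reconstruction.

Pipeline: marching-cubes surface from the binary mask, Laplacian smoothing,
attraction-repulsion mapping of the mesh onto the unit sphere, least-squares
spherical-harmonic expansion of the three coordinate functions, and one
reconstruction-error value per harmonic degree (70 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.linalg import solve_triangular
from scipy.linalg.blas import dsyrk
from skimage import measure

from .config import ARConfig, Config, MorphConfig
from .errors import (
    BadAngleError,
    DegenerateMeshError,
    DuplicateNodeError,
    InsufficientNodesError,
)
from .study import TumorStudy

MIN_MASK_VOXELS = 20


# ---------------------------------------------------------------------------
# mesh
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Closed triangulated surface in millimetre coordinates."""

    nodes: np.ndarray  # (I, 3) float
    triangles: np.ndarray  # (F, 3) int

    _adj: Optional[sparse.csr_matrix] = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) index array."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric 0/1 node adjacency matrix."""
        if self._adj is None:
            e = self.edges()
            i = np.concatenate([e[:, 0], e[:, 1]])
            j = np.concatenate([e[:, 1], e[:, 0]])
            self._adj = sparse.csr_matrix(
                (np.ones(len(i)), (i, j)), shape=(self.n_nodes, self.n_nodes)
            )
        return self._adj

    def neighbor_counts(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel()

    def euler_characteristic(self) -> int:
        return self.n_nodes - len(self.edges()) + len(self.triangles)

    def is_closed(self) -> bool:
        """Every edge is shared by exactly two triangles."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def surface_area(self) -> float:
        p = self.nodes[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    def centroid(self) -> np.ndarray:
        return self.nodes.mean(axis=0)


@dataclass
class SphericalMap:
    """Per-node unit vectors in one-one correspondence with mesh nodes."""

    points: np.ndarray  # (I, 3), unit norm
    n_iters: int
    converged: bool = True

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.points, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("spherical-map points must be unit vectors")

    @property
    def theta(self) -> np.ndarray:
        """Polar angle in [0, pi]."""
        return np.arccos(np.clip(self.points[:, 2], -1.0, 1.0))

    @property
    def phi(self) -> np.ndarray:
        """Azimuth in [0, 2*pi)."""
        return np.mod(np.arctan2(self.points[:, 1], self.points[:, 0]), 2 * np.pi)


ARParams = ARConfig  # the config dataclass doubles as the parameter record


def mask_to_mesh(
    mask: np.ndarray,
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
    smooth_iters: int = 10,
    smooth_factor: float = 0.5,
) -> SurfaceMesh:
    """Extract a closed genus-0 surface from a binary mask.

    The mask is padded by one voxel so marching cubes always closes the
    surface; vertices are returned in mm via the voxel spacing.
    """
    mask = np.asarray(mask) > 0
    if mask.sum() < MIN_MASK_VOXELS:
        raise DegenerateMeshError(
            f"mesh degenerate: only {int(mask.sum())} foreground voxels"
        )
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    verts = verts - np.asarray(spacing, dtype=float)  # undo padding shift
    mesh = SurfaceMesh(np.ascontiguousarray(verts, dtype=float), faces.astype(np.intp))
    if not mesh.is_closed() or mesh.euler_characteristic() != 2:
        raise DegenerateMeshError(
            "mesh degenerate: extracted surface is not a closed genus-0 mesh"
        )
    if np.any(mesh.neighbor_counts() < 3):
        raise DegenerateMeshError("mesh degenerate: node with < 3 neighbors")
    if smooth_iters > 0:
        mesh = laplacian_smooth(mesh, iters=smooth_iters, factor=smooth_factor)
    return mesh


def laplacian_smooth(mesh: SurfaceMesh, iters: int = 10, factor: float = 0.5) -> SurfaceMesh:
    """Umbrella-operator smoothing: move each node toward its neighbor mean."""
    adj = mesh.adjacency()
    deg = np.asarray(adj.sum(axis=1)).ravel()[:, None]
    nodes = mesh.nodes.copy()
    for _ in range(iters):
        nodes += factor * (adj @ nodes / deg - nodes)
    return SurfaceMesh(nodes, mesh.triangles, _adj=adj)


def subdivide(
    mesh: SurfaceMesh, smap: Optional[SphericalMap] = None
) -> Tuple[SurfaceMesh, Optional[SphericalMap]]:
    """Midpoint 1-to-4 subdivision; the spherical map (if given) is
    subdivided consistently with new points renormalized onto the sphere."""
    edges = mesh.edges()
    edge_index: Dict[Tuple[int, int], int] = {
        (int(a), int(b)): mesh.n_nodes + k for k, (a, b) in enumerate(edges)
    }
    mid = 0.5 * (mesh.nodes[edges[:, 0]] + mesh.nodes[edges[:, 1]])
    nodes = np.vstack([mesh.nodes, mid])

    tris: List[Tuple[int, int, int]] = []
    for a, b, c in mesh.triangles:
        ab = edge_index[tuple(sorted((int(a), int(b))))]
        bc = edge_index[tuple(sorted((int(b), int(c))))]
        ca = edge_index[tuple(sorted((int(c), int(a))))]
        tris += [(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)]
    new_mesh = SurfaceMesh(nodes, np.array(tris, dtype=np.intp))

    new_map = None
    if smap is not None:
        pmid = 0.5 * (smap.points[edges[:, 0]] + smap.points[edges[:, 1]])
        pmid /= np.linalg.norm(pmid, axis=1, keepdims=True)
        new_map = SphericalMap(
            np.vstack([smap.points, pmid]), smap.n_iters, smap.converged
        )
    return new_mesh, new_map


def refine_to_count(
    mesh: SurfaceMesh, smap: Optional[SphericalMap], target: int
) -> Tuple[SurfaceMesh, Optional[SphericalMap]]:
    """Split longest edges (2-triangle bisection) until ``target`` nodes.

    Adds only as many nodes as needed (unlike the 1-to-4 subdivision, which
    quadruples the triangle count), keeping the least-squares fit close to
    square.  Each split bisects one edge and its two adjacent triangles;
    edges sharing a triangle are never split in the same pass.
    """
    while mesh.n_nodes < target:
        nodes = list(map(tuple, mesh.nodes))
        spts = None if smap is None else [tuple(p) for p in smap.points]
        tris = {i: tuple(t) for i, t in enumerate(mesh.triangles)}
        edge_tris: Dict[Tuple[int, int], List[int]] = {}
        for ti, (a, b, c) in tris.items():
            for e in ((a, b), (b, c), (c, a)):
                edge_tris.setdefault(tuple(sorted(map(int, e))), []).append(ti)
        pts = mesh.nodes
        lengths = {
            e: np.linalg.norm(pts[e[0]] - pts[e[1]]) for e in edge_tris
        }
        used: set = set()
        extra: List[Tuple[int, int, int]] = []
        n_new = 0
        for e in sorted(lengths, key=lengths.get, reverse=True):
            if mesh.n_nodes + n_new >= target:
                break
            t_ids = edge_tris[e]
            if len(t_ids) != 2 or any(t in used for t in t_ids):
                continue
            mid_idx = len(nodes)
            nodes.append(tuple(0.5 * (pts[e[0]] + pts[e[1]])))
            if spts is not None:
                pm = 0.5 * (smap.points[e[0]] + smap.points[e[1]])
                spts.append(tuple(pm / np.linalg.norm(pm)))
            for ti in t_ids:
                tri = tris[ti]
                # rotate so the split edge is (tri[0], tri[1])
                for _ in range(3):
                    if {tri[0], tri[1]} == set(e):
                        break
                    tri = (tri[1], tri[2], tri[0])
                x, y, z = tri
                tris[ti] = (x, mid_idx, z)
                extra.append((mid_idx, y, z))
                used.add(ti)
            n_new += 1
        if n_new == 0:  # no independent splittable edge left this pass
            mesh, smap = subdivide(mesh, smap)
            continue
        new_tris = np.array(list(tris.values()) + extra, dtype=np.intp)
        mesh = SurfaceMesh(np.array(nodes), new_tris)
        if smap is not None:
            smap = SphericalMap(np.array(spts), smap.n_iters, smap.converged)
    return mesh, smap


# ---------------------------------------------------------------------------
# attraction-repulsion spherical parameterization
# ---------------------------------------------------------------------------


def _repulsion_field(points: np.ndarray, chunk: int = 4096) -> np.ndarray:
    """sum_{j != i} (p_i - p_j) / ||p_i - p_j||^2 for every node i.

    Uses the identity sum_j w_ij (p_i - p_j) = p_i * (sum_j w_ij) - W @ P
    with w_ij = 1 / d_ij^2 so the inner loops run as BLAS matmuls; squared
    distances come from the Gram matrix, in row chunks to bound memory.
    """
    n = len(points)
    p32 = points.astype(np.float32)  # field only steers a smoothing flow
    sq = np.einsum("ij,ij->i", p32, p32)
    out = np.empty_like(points)
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        d2 = sq[s:e, None] + sq[None, :] - 2.0 * (p32[s:e] @ p32.T)
        np.maximum(d2, 0.0, out=d2)
        rows = np.arange(e - s)
        d2[rows, np.arange(s, e)] = np.inf
        if np.any(d2 < 1e-12):
            raise DuplicateNodeError("duplicate node: coincident points on sphere")
        w = 1.0 / d2
        out[s:e] = p32[s:e] * w.sum(axis=1)[:, None] - w @ p32
    return out


def initial_spherical_map(mesh: SurfaceMesh) -> np.ndarray:
    """Centroid-centered radial projection of mesh nodes onto the unit sphere."""
    centered = mesh.nodes - mesh.centroid()
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise DuplicateNodeError("duplicate node: node at mesh centroid")
    points = centered / norms
    if len(np.unique(points, axis=0)) != len(points):
        raise DuplicateNodeError("duplicate node: coincident points on sphere")
    return points


def attraction_repulsion(mesh: SurfaceMesh, params: Optional[ARParams] = None) -> SphericalMap:
    """Map the mesh one-one onto the unit sphere.

    Each iteration applies a per-node attraction toward neighbors, a global
    pairwise repulsion that inflates the mesh, and a projection back onto
    the sphere; it stops when the largest node displacement drops below the
    threshold.  The repulsion displacements are recomputed from the
    post-attraction positions unless ``params.literal_alpha`` is set.
    """
    if params is None:
        params = ARParams()
    points = initial_spherical_map(mesh)
    edges = mesh.edges()
    src = np.concatenate([edges[:, 0], edges[:, 1]])
    dst = np.concatenate([edges[:, 1], edges[:, 0]])
    n = len(points)

    converged = False
    alpha = 0
    for alpha in range(1, params.max_iters + 1):
        # attraction: keep each node centered among its mesh neighbors
        d_vec = points[dst] - points[src]  # displacement i -> j per directed edge
        d = np.linalg.norm(d_vec, axis=1)
        if np.any(d == 0):
            raise DuplicateNodeError("duplicate node: zero neighbor distance")
        contrib = d_vec * (d**2)[:, None] + params.ca2 * d_vec / d[:, None]
        acc = np.zeros_like(points)
        np.add.at(acc, src, contrib)
        attracted = points + params.ca1 * acc

        # repulsion: push every node away from all others
        base = points if params.literal_alpha else attracted
        repelled = attracted + (params.cr / (2 * n)) * _repulsion_field(base)

        new_points = repelled / np.linalg.norm(repelled, axis=1, keepdims=True)
        step = np.max(np.linalg.norm(new_points - points, axis=1))
        points = new_points
        if step <= params.threshold:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"attraction-repulsion did not reach threshold {params.threshold} "
            f"in {params.max_iters} iterations; returning best map",
            RuntimeWarning,
            stacklevel=2,
        )
    return SphericalMap(points, n_iters=alpha, converged=converged)


def _syrk(a: np.ndarray) -> np.ndarray:
    """Symmetric A^T A via BLAS dsyrk (half the flops of a full gemm)."""
    g = dsyrk(1.0, np.asfortranarray(a), trans=1)
    return g + np.triu(g, 1).T


# ---------------------------------------------------------------------------
# real spherical harmonics
# ---------------------------------------------------------------------------


def sh_basis(theta: np.ndarray, phi: np.ndarray, l_max: int) -> np.ndarray:
    """Real orthonormal spherical-harmonic design matrix.

    Returns an ``(n_points, (l_max+1)**2)`` array with columns ordered by
    degree tau = 0..l_max and, within a degree, by order
    beta = -tau..tau (sine harmonics, zonal, cosine harmonics).  Associated
    Legendre values are generated by the standard fully-normalized stable
    recurrence, evaluated at cos(theta), without the Condon-Shortley phase.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    if theta.shape != phi.shape:
        raise BadAngleError("bad angle: theta and phi shapes differ")
    if np.any(theta < 0) or np.any(theta > np.pi):
        raise BadAngleError("bad angle: theta outside [0, pi]")
    if np.any(phi < 0) or np.any(phi >= 2 * np.pi):
        raise BadAngleError("bad angle: phi outside [0, 2*pi)")
    if l_max < 0:
        raise ValueError("l_max must be >= 0")

    n = len(theta)
    x = np.cos(theta)
    sin_t = np.sin(theta)
    n_basis = (l_max + 1) ** 2
    out = np.empty((n, n_basis))

    def col(tau: int, beta: int) -> int:
        return tau * tau + (beta + tau)

    sqrt2 = np.sqrt(2.0)
    # normalized P~_l^m with integral of (P~)^2 over the sphere (with the
    # 2*pi azimuthal factor folded in) equal to 1 for m = 0
    pmm = np.full(n, np.sqrt(1.0 / (4 * np.pi)))
    for m in range(l_max + 1):
        if m > 0:
            pmm = pmm * sin_t * np.sqrt((2 * m + 1) / (2.0 * m))
        if m == 0:
            cos_m = None
            sin_m = None
        else:
            cos_m = sqrt2 * np.cos(m * phi)
            sin_m = sqrt2 * np.sin(m * phi)

        def emit(tau: int, p: np.ndarray) -> None:
            if m == 0:
                out[:, col(tau, 0)] = p
            else:
                out[:, col(tau, m)] = p * cos_m
                out[:, col(tau, -m)] = p * sin_m

        emit(m, pmm)
        if m == l_max:
            break
        p_prev = pmm
        p_curr = x * np.sqrt(2.0 * m + 3) * pmm
        emit(m + 1, p_curr)
        for tau in range(m + 2, l_max + 1):
            a = np.sqrt((4.0 * tau * tau - 1) / (tau * tau - m * m))
            b = np.sqrt(((tau - 1.0) ** 2 - m * m) / (4.0 * (tau - 1) ** 2 - 1))
            p_next = a * (x * p_curr - b * p_prev)
            emit(tau, p_next)
            p_prev, p_curr = p_curr, p_next
    return out


@dataclass
class SHExpansion:
    """Least-squares harmonic fit of the coordinate functions on the sphere."""

    l_max: int
    coefficients: np.ndarray  # ((l_max+1)**2, 3)
    errors: np.ndarray  # (l_max,) per-degree reconstruction errors

    def __post_init__(self) -> None:
        if len(self.coefficients) != (self.l_max + 1) ** 2:
            raise ValueError("coefficient count must be (l_max+1)**2")


def sh_reconstruction_errors(
    mesh: SurfaceMesh,
    smap: SphericalMap,
    l_max: int = 70,
    normalize: bool = False,
    return_expansion: bool = False,
):
    """Per-degree reconstruction errors of the centroid-relative surface.

    Fits the three coordinate functions on the sphere with harmonics up to
    ``l_max`` via one degree-ordered QR factorization; the error at degree d
    is the sum over nodes of the Euclidean distance between the original
    node and its reconstruction from harmonics of degree <= d.
    """
    n_basis = (l_max + 1) ** 2
    if mesh.n_nodes < n_basis:
        raise InsufficientNodesError(
            f"insufficient nodes: {mesh.n_nodes} < {n_basis} basis functions"
        )
    target = mesh.nodes - mesh.centroid()  # translation invariance
    basis = sh_basis(smap.theta, smap.phi, l_max)

    errors = np.empty(l_max)
    coeffs = None
    try:
        # nested-prefix fits from one Cholesky factor of the Gram matrix:
        # the leading k x k block of L factors the leading block of A^T A
        gram = _syrk(basis)
        chol = np.linalg.cholesky(gram)
        aty = basis.T @ target
        for d in range(1, l_max + 1):
            k = (d + 1) ** 2
            lk = chol[:k, :k]
            c = solve_triangular(
                lk.T, solve_triangular(lk, aty[:k], lower=True, check_finite=False),
                lower=False, check_finite=False,
            )
            resid = target - basis[:, :k] @ c
            errors[d - 1] = np.linalg.norm(resid, axis=1).sum()
        if return_expansion:
            coeffs = c
    except np.linalg.LinAlgError:
        # ill-conditioned sampling: fall back to the degree-ordered QR route
        q, r = np.linalg.qr(basis)
        z = q.T @ target
        k_prev = 1
        recon = q[:, :1] @ z[:1]
        for d in range(1, l_max + 1):
            k = (d + 1) ** 2
            recon += q[:, k_prev:k] @ z[k_prev:k]
            errors[d - 1] = np.linalg.norm(target - recon, axis=1).sum()
            k_prev = k
        if return_expansion:
            coeffs = np.linalg.solve(r, z)
    if normalize:
        errors = errors / mesh.n_nodes
    if return_expansion:
        return errors, SHExpansion(l_max, coeffs, errors)
    return errors


def morphological_markers(study: TumorStudy, cfg: Optional[Config] = None) -> Dict[str, float]:
    """70 (by default) named per-degree reconstruction-error markers."""
    if cfg is None:
        cfg = Config.default()
    m: MorphConfig = cfg.morph
    mesh = mask_to_mesh(
        study.mask,
        spacing=study.spacing,
        smooth_iters=m.smooth.iters,
        smooth_factor=m.smooth.factor,
    )
    smap = attraction_repulsion(mesh, m.ar)
    n_basis = (m.l_max + 1) ** 2
    if mesh.n_nodes < n_basis:
        mesh, smap = refine_to_count(mesh, smap, n_basis)
    errors = sh_reconstruction_errors(mesh, smap, m.l_max, normalize=m.normalize_errors)
    return {f"SH_err_{d:03d}": float(errors[d - 1]) for d in range(1, m.l_max + 1)}


def morphological_marker_names(l_max: int = 70) -> List[str]:
    return [f"SH_err_{d:03d}" for d in range(1, l_max + 1)]
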