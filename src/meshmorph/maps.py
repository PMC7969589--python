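"""Localized shape-difference fields on meshes.

Per-vertex displacement, signed distance to another surface (negative inside
the target), local surface stretch between corresponding meshes, 3-D thin-
plate-spline warps from landmarks, and linear morph frame sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConsistencyError, DegenerateInputError, ParameterError
from .mesh import TriMesh, write_mesh

__all__ = [
    "VertexMap",
    "TpsWarp",
    "displacement_map",
    "signed_distance_map",
    "stretch_map",
    "tps_fit",
    "tps_apply",
    "morph_frames",
    "write_vertex_map",
]


@dataclass
class VertexMap:
    """One scalar per vertex of a mesh (heatmap payload)."""

    mesh: TriMesh
    values: np.ndarray
    kind: str = "displacement"  # displacement | signed_distance | stretch

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float).ravel()
        if len(self.values) != self.mesh.n_vertices:
            raise ConsistencyError("one value per vertex required")


def write_vertex_map(vmap: VertexMap, path: str | Path, csv_path: str | Path | None = None) -> None:
    """Write the scalar as a per-vertex property in ASCII PLY, and optionally
    a (vertex_id, value) CSV."""
    mesh = vmap.mesh.copy()
    mesh.scalars = vmap.values.copy()
    write_mesh(mesh, path)
    if csv_path is not None:
        lines = ["vertex_id,value"]
        lines += [f"{i},{float(v)!r}" for i, v in enumerate(vmap.values)]
        Path(csv_path).write_text("\n".join(lines) + "\n")


def _check_correspondence(mesh_a: TriMesh, mesh_b: TriMesh) -> None:
    if mesh_a.n_vertices != mesh_b.n_vertices or not np.array_equal(
        mesh_a.faces, mesh_b.faces
    ):
        raise ConsistencyError("meshes must share vertex count and face structure")


def displacement_map(mesh_a: TriMesh, mesh_b: TriMesh) -> VertexMap:
    """Unsigned per-vertex displacement ``||B_v - A_v||`` between
    corresponding meshes (net movement, direction-agnostic)."""
    _check_correspondence(mesh_a, mesh_b)
    d = np.linalg.norm(mesh_b.vertices - mesh_a.vertices, axis=1)
    return VertexMap(mesh_a, d, kind="displacement")


# ---------------------------------------------------------------------------
# signed distance (meshdist semantics: negative inside the target)
# ---------------------------------------------------------------------------


def _closest_point_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Min distance from each point to a triangle soup (P,) — vectorised
    plane-projection with edge clamping."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    n = np.cross(b - a, c - a)
    nn = (n**2).sum(1)
    nn_safe = np.where(nn > 0, nn, 1.0)

    P = points[:, None, :]  # (P,1,3)
    ap = P - a[None, :, :]
    # barycentric coordinates of the plane projection:
    # d1 is the weight along (b-a), d2 along (c-a); at p=b, (b-a).((c-a)xn)=|n|^2
    d1 = np.einsum("pfd,fd->pf", P - a[None], np.cross(c - a, n)) / nn_safe
    d2 = np.einsum("pfd,fd->pf", P - a[None], np.cross(n, b - a)) / nn_safe
    inside = (d1 >= 0) & (d2 >= 0) & (d1 + d2 <= 1)
    t_plane = np.einsum("pfd,fd->pf", ap, n) / np.sqrt(nn_safe)
    dist_plane = np.abs(t_plane)

    def seg_dist(p0, p1):
        d = p1 - p0  # (F,3)
        dd = (d**2).sum(1)
        dd_safe = np.where(dd > 0, dd, 1.0)
        t = np.clip(np.einsum("pfd,fd->pf", P - p0[None], d) / dd_safe, 0.0, 1.0)
        proj = p0[None] + t[..., None] * d[None]
        return np.linalg.norm(P - proj, axis=-1)

    d_edges = np.minimum(seg_dist(a, b), np.minimum(seg_dist(b, c), seg_dist(c, a)))
    return np.min(np.where(inside, dist_plane, d_edges), axis=1)


def _ray_parity_inside(points: np.ndarray, mesh: TriMesh) -> np.ndarray:
    """Inside test by counting ray crossings (Moeller-Trumbore, fixed
    irrational direction to dodge edge-grazing degeneracies)."""
    direction = np.array([0.577350269189626, 0.577350269189626 + 1e-4, 0.577350269189626 - 2e-4])
    direction /= np.linalg.norm(direction)
    tri = mesh.triangles()
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    h = np.cross(direction, e2)  # (F,3)
    det = np.einsum("fd,fd->f", e1, h)
    ok = np.abs(det) > 1e-14
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = points[:, None, :] - v0[None]  # (P,F,3)
    u = np.einsum("pfd,fd->pf", s, h) * inv[None]
    q = np.cross(s, e1[None])
    v = np.einsum("pfd,d->pf", q, direction) * inv[None]
    t = np.einsum("pfd,fd->pf", q, e2) * inv[None]
    hit = ok[None] & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-12)
    return (hit.sum(axis=1) % 2).astype(bool)


def signed_distance_map(reference: TriMesh, target: TriMesh, chunk: int = 2048) -> VertexMap:
    """For each reference vertex: distance to the nearest point of the target
    surface, negated when the vertex lies inside the target.

    A non-watertight target cannot support the inside test; the sign then
    falls back to the outward-normal dot product at the nearest face, with a
    warning.
    """
    pts = reference.vertices
    tri = target.triangles()
    dist = np.empty(len(pts))
    for i in range(0, len(pts), chunk):
        dist[i : i + chunk] = _closest_point_on_triangles(pts[i : i + chunk], tri)
    if target.is_watertight():
        inside = np.zeros(len(pts), bool)
        for i in range(0, len(pts), chunk):
            inside[i : i + chunk] = _ray_parity_inside(pts[i : i + chunk], target)
    else:
        warnings.warn(
            "target is not watertight; using normal-dot-product sign",
            RuntimeWarning,
            stacklevel=2,
        )
        centers = target.face_centers()
        normals = target.face_area_normals()
        inside = np.zeros(len(pts), bool)
        for i in range(0, len(pts), chunk):
            block = pts[i : i + chunk]
            nearest = np.argmin(
                ((block[:, None, :] - centers[None]) ** 2).sum(-1), axis=1
            )
            inside[i : i + chunk] = (
                np.einsum("pd,pd->p", block - centers[nearest], normals[nearest]) < 0
            )
    values = np.where(inside, -dist, dist)
    return VertexMap(reference, values, kind="signed_distance")


# ---------------------------------------------------------------------------
# local stretch
# ---------------------------------------------------------------------------


def stretch_map(mesh_a: TriMesh, mesh_b: TriMesh, method: str = "area") -> VertexMap:
    """Local surface stretch between corresponding meshes.

    ``method='area'`` (default): per-vertex ratio of summed incident triangle
    areas, B over A — a uniform scale ``s`` gives exactly ``s**2``
    everywhere.  ``method='edge'``: ratio of mean incident edge lengths,
    which scales as ``s`` instead.  Values > 1 mark local expansion, < 1
    shrinkage; no global scaling is applied.
    """
    _check_correspondence(mesh_a, mesh_b)
    if method not in ("area", "edge"):
        raise ParameterError("method must be 'area' or 'edge'")
    faces = mesh_a.faces
    nv = mesh_a.n_vertices
    if method == "area":
        num = np.zeros(nv)
        den = np.zeros(nv)
        areas_a = mesh_a.face_areas()
        areas_b = mesh_b.face_areas()
        for i in range(3):
            np.add.at(den, faces[:, i], areas_a)
            np.add.at(num, faces[:, i], areas_b)
    else:
        e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
        e = np.unique(np.sort(e, axis=1), axis=0)
        la = np.linalg.norm(mesh_a.vertices[e[:, 0]] - mesh_a.vertices[e[:, 1]], axis=1)
        lb = np.linalg.norm(mesh_b.vertices[e[:, 0]] - mesh_b.vertices[e[:, 1]], axis=1)
        num = np.zeros(nv)
        den = np.zeros(nv)
        for i in range(2):
            np.add.at(den, e[:, i], la)
            np.add.at(num, e[:, i], lb)
    if np.any(den == 0):
        raise DegenerateInputError(
            "vertex with zero incident measure in the reference mesh"
        )
    return VertexMap(mesh_a, num / den, kind="stretch")


# ---------------------------------------------------------------------------
# thin-plate-spline warp (3-D, kernel U(r) = r)
# ---------------------------------------------------------------------------


@dataclass
class TpsWarp:
    """3-D thin-plate spline interpolating source landmarks onto targets.

    Uses the 3-D biharmonic kernel ``U(r) = r``.  The kernel weights satisfy
    the side conditions ``sum w = 0`` and ``sum w x = 0``, so a purely affine
    landmark relation yields zero kernel weights.
    """

    source_landmarks: np.ndarray
    target_landmarks: np.ndarray
    affine: np.ndarray  # (4,3): rows = [translation; linear part]
    weights: np.ndarray  # (K,3)

    def bending_weights_norm(self) -> float:
        return float(np.linalg.norm(self.weights))


def tps_fit(source_lms: np.ndarray, target_lms: np.ndarray) -> TpsWarp:
    """Fit a 3-D TPS mapping source landmarks exactly onto targets."""
    src = np.asarray(source_lms, float).reshape(-1, 3)
    dst = np.asarray(target_lms, float).reshape(-1, 3)
    if src.shape != dst.shape:
        raise ConsistencyError("source and target landmark counts differ")
    k = len(src)
    if k < 5:
        raise ParameterError("3-D TPS needs at least 5 landmarks")
    P = np.hstack([np.ones((k, 1)), src])
    if np.linalg.matrix_rank(P, tol=1e-9 * max(1.0, np.abs(src).max())) < 4:
        raise DegenerateInputError("landmarks are coplanar; 3-D TPS is rank-deficient")
    U = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=-1)  # U(r) = r
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = U
    L[:k, k:] = P
    L[k:, :k] = P.T
    rhs = np.zeros((k + 4, 3))
    rhs[:k] = dst
    sol = np.linalg.solve(L, rhs)
    return TpsWarp(src, dst, affine=sol[k:], weights=sol[:k])


def tps_apply(warp: TpsWarp, points: np.ndarray) -> np.ndarray:
    """Evaluate a fitted TPS warp at arbitrary points."""
    pts = np.asarray(points, float).reshape(-1, 3)
    U = np.linalg.norm(pts[:, None, :] - warp.source_landmarks[None, :, :], axis=-1)
    P = np.hstack([np.ones((len(pts), 1)), pts])
    return U @ warp.weights + P @ warp.affine


# ---------------------------------------------------------------------------
# morph sequences
# ---------------------------------------------------------------------------


def morph_frames(
    mesh_a: TriMesh, mesh_b: TriMesh, n_frames: int = 10, exaggeration: float = 1.0
) -> list[TriMesh]:
    """Linear morph from A toward B: frame t has vertices
    ``A + exaggeration * t * (B - A)`` for t evenly spaced on [0, 1]."""
    _check_correspondence(mesh_a, mesh_b)
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    delta = mesh_b.vertices - mesh_a.vertices
    frames = []
    for t in np.linspace(0.0, 1.0, n_frames):
        frames.append(
            TriMesh(mesh_a.vertices + exaggeration * t * delta, mesh_a.faces.copy())
        )
    return frames
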