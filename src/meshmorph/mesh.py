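"""Triangle-mesh data model, I/O, cleaning, smoothing, decimation and size measures.

The :class:`TriMesh` is the unit of all shape computation in this package:
a vertex array in physical millimetres and a face index array.  ASCII PLY is
the canonical interchange dialect (written at full ``repr`` precision so
write→read roundtrips are bit-exact); OBJ, STL and binary PLY are read and
written through :mod:`trimesh`.
"""

from __future__ import annotations

import heapq
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

from .errors import EmptyInputError, FormatError, ParameterError

__all__ = [
    "TriMesh",
    "SizeReport",
    "read_mesh",
    "write_mesh",
    "clean_mesh",
    "laplacian_smooth",
    "decimate",
    "centroid_size",
]


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class TriMesh:
    """Triangulated surface with vertices in mm and an optional scalar channel.

    Parameters
    ----------
    vertices : (N, 3) float array
        Vertex coordinates in physical millimetres.
    faces : (M, 3) int array
        Vertex indices of each triangle, counter-clockwise seen from outside.
    scalars : (N,) float array, optional
        One per-vertex scalar channel (heatmap values etc.).
    """

    vertices: np.ndarray
    faces: np.ndarray
    scalars: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ParameterError("face indices out of range")
        if self.scalars is not None:
            self.scalars = np.asarray(self.scalars, dtype=float).ravel()
            if len(self.scalars) != len(self.vertices):
                raise ParameterError("scalar channel length must match vertex count")

    # -- derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(M, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_centers(self) -> np.ndarray:
        return self.triangles().mean(axis=1)

    def face_area_normals(self) -> np.ndarray:
        """Area-weighted normals ``0.5 * (v1-v0) x (v2-v0)``; norm equals area."""
        t = self.triangles()
        return 0.5 * np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])

    def face_areas(self) -> np.ndarray:
        return np.linalg.norm(self.face_area_normals(), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def edges_sorted(self) -> np.ndarray:
        """(3M, 2) undirected edges, each sorted, one row per face side."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.sort(e, axis=1)

    def euler_characteristic(self) -> int:
        unique_edges = np.unique(self.edges_sorted(), axis=0)
        return self.n_vertices - len(unique_edges) + self.n_faces

    def is_watertight(self) -> bool:
        """True iff every undirected edge is shared by exactly two faces."""
        if self.n_faces == 0:
            return False
        _, counts = np.unique(self.edges_sorted(), axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def vertex_normals(self) -> np.ndarray:
        """Unit outward vertex normals (area-weighted average of face normals)."""
        fn = self.face_area_normals()
        vn = np.zeros_like(self.vertices)
        for i in range(3):
            np.add.at(vn, self.faces[:, i], fn)
        norms = np.linalg.norm(vn, axis=1, keepdims=True)
        return vn / np.where(norms > 0, norms, 1.0)

    def signed_volume(self) -> float:
        """Signed enclosed volume (positive for outward-oriented closed meshes)."""
        t = self.triangles()
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.scalars is None else self.scalars.copy(),
        )

    def vertex_adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR-style 1-ring adjacency: (indptr, neighbour indices)."""
        e = np.unique(self.edges_sorted(), axis=0)
        src = np.concatenate([e[:, 0], e[:, 1]])
        dst = np.concatenate([e[:, 1], e[:, 0]])
        order = np.argsort(src, kind="stable")
        src, dst = src[order], dst[order]
        indptr = np.searchsorted(src, np.arange(self.n_vertices + 1))
        return indptr, dst

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, tm: _trimesh.Trimesh) -> "TriMesh":
        return cls(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))


@dataclass
class SizeReport:
    """Centroid size of a point configuration.

    ``centroid_size`` is the square root of the summed squared distances of
    the points to their centroid; ``normalized_centroid_size`` divides it by
    the number of points so that configurations sampled at different densities
    become loosely comparable (they remain strictly comparable only within a
    fixed point-count scheme).
    """

    centroid_size: float
    normalized_centroid_size: float
    n_points: int


def centroid_size(points: np.ndarray) -> SizeReport:
    """Centroid size ``sqrt(sum_i ||x_i - mean||^2)`` of an (N, 3) point array."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 1:
        raise EmptyInputError("centroid_size requires at least one point")
    cs = float(np.sqrt(((pts - pts.mean(axis=0)) ** 2).sum()))
    return SizeReport(cs, cs / len(pts), len(pts))


# ---------------------------------------------------------------------------
# I/O — canonical ASCII PLY plus trimesh-backed formats
# ---------------------------------------------------------------------------

_SCALAR_PROP = "quality"  # MeshLab-compatible name for the scalar channel


def _write_ply_ascii(mesh: TriMesh, path: Path) -> None:
    buf = io.StringIO()
    buf.write("ply\nformat ascii 1.0\ncomment meshmorph\n")
    buf.write(f"element vertex {mesh.n_vertices}\n")
    buf.write("property double x\nproperty double y\nproperty double z\n")
    if mesh.scalars is not None:
        buf.write(f"property double {_SCALAR_PROP}\n")
    buf.write(f"element face {mesh.n_faces}\n")
    buf.write("property list uchar int vertex_indices\nend_header\n")
    if mesh.scalars is None:
        for v in mesh.vertices:
            buf.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
    else:
        for v, s in zip(mesh.vertices, mesh.scalars):
            buf.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r} {float(s)!r}\n")
    for f in mesh.faces:
        buf.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    path.write_text(buf.getvalue())


def _read_ply_ascii(path: Path) -> TriMesh:
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise FormatError(f"{path}: not a PLY file (missing 'ply' magic on line 1)")
    n_vert = n_face = None
    vert_props: list[str] = []
    current_element = None
    i = 1
    header_done = False
    for i, line in enumerate(lines[1:], start=1):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            if tok[1] != "ascii":
                raise FormatError(f"{path}: line {i + 1}: only ascii handled here")
        elif tok[0] == "element":
            current_element = tok[1]
            if tok[1] == "vertex":
                n_vert = int(tok[2])
            elif tok[1] == "face":
                n_face = int(tok[2])
        elif tok[0] == "property" and current_element == "vertex" and tok[1] != "list":
            vert_props.append(tok[-1])
        elif tok[0] == "end_header":
            header_done = True
            break
    if not header_done or n_vert is None or n_face is None:
        raise FormatError(f"{path}: truncated PLY header (no end_header by line {i + 1})")
    body = lines[i + 1 :]
    if len(body) < n_vert + n_face:
        raise FormatError(
            f"{path}: expected {n_vert + n_face} data lines after header, got {len(body)}"
        )
    try:
        vdata = np.array([[float(x) for x in body[j].split()] for j in range(n_vert)])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed vertex line: {exc}") from exc
    cols = {p: k for k, p in enumerate(vert_props)}
    verts = vdata[:, [cols["x"], cols["y"], cols["z"]]] if n_vert else np.zeros((0, 3))
    scalars = vdata[:, cols[_SCALAR_PROP]] if _SCALAR_PROP in cols and n_vert else None
    faces = []
    for j in range(n_vert, n_vert + n_face):
        tok = body[j].split()
        cnt = int(tok[0])
        if cnt != 3:
            raise FormatError(f"{path}: non-triangular face with {cnt} vertices")
        faces.append([int(tok[1]), int(tok[2]), int(tok[3])])
    return TriMesh(verts, np.array(faces, np.int64).reshape(-1, 3), scalars)


def read_mesh(path: str | Path, format: str | None = None) -> TriMesh:
    """Read a PLY/OBJ/STL surface mesh.

    ASCII PLY goes through the package's own full-precision parser; binary
    PLY, OBJ and STL are delegated to :mod:`trimesh`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in {"ply", "obj", "stl"}:
        raise FormatError(f"{path}: unknown mesh format {fmt!r}")
    if fmt == "ply":
        with open(path, "rb") as fh:
            head = fh.read(256)
        if b"format ascii" in head:
            return _read_ply_ascii(path)
    try:
        tm = _trimesh.load(str(path), file_type=fmt, force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - normalise third-party parse errors
        raise FormatError(f"{path}: malformed {fmt} file: {exc}") from exc
    return TriMesh.from_trimesh(tm)


def write_mesh(mesh: TriMesh, path: str | Path, format: str | None = None) -> None:
    """Write a mesh; ``.ply`` is ASCII at full precision (canonical dialect)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        _write_ply_ascii(mesh, path)
    elif fmt in {"obj", "stl"}:
        mesh.to_trimesh().export(str(path), file_type=fmt)
    else:
        raise FormatError(f"{path}: unknown mesh format {fmt!r}")


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------


def clean_mesh(mesh: TriMesh, merge_tol: float = 1e-6) -> TriMesh:
    """Merge close vertices, drop degenerate/duplicate faces and faces on
    non-manifold edges, and discard unreferenced vertices.

    ``merge_tol`` is the merge distance in mm (vertices are snapped to a grid
    of that pitch; 0 merges exact duplicates only).  Idempotent.
    """
    if merge_tol < 0:
        raise ParameterError("merge_tol must be >= 0")
    verts, faces = mesh.vertices, mesh.faces
    if len(verts) == 0:
        return mesh.copy()

    # merge close vertices by grid quantisation, keeping first-occurrence order
    key = verts if merge_tol == 0 else np.round(verts / merge_tol)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)
    rank = np.empty(len(order), np.int64)
    rank[order] = np.arange(len(order))
    verts = verts[first[order]]
    faces = rank[inverse][faces] if len(faces) else faces

    if len(faces):
        # degenerate: repeated indices or zero area
        distinct = (
            (faces[:, 0] != faces[:, 1])
            & (faces[:, 1] != faces[:, 2])
            & (faces[:, 0] != faces[:, 2])
        )
        faces = faces[distinct]
    if len(faces):
        t = verts[faces]
        areas = np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)
        faces = faces[areas > 0]
    if len(faces):
        # duplicate faces (same vertex set, either orientation)
        _, keep = np.unique(np.sort(faces, axis=1), axis=0, return_index=True)
        faces = faces[np.sort(keep)]
    if len(faces):
        # faces incident to edges shared by >2 faces
        e = np.sort(
            np.concatenate(
                [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]
            ),
            axis=1,
        )
        uniq, inv, counts = np.unique(e, axis=0, return_inverse=True, return_counts=True)
        bad_edge = counts > 2
        bad_face = bad_edge[inv].reshape(3, -1).any(axis=0)
        faces = faces[~bad_face]

    # drop unreferenced vertices
    used = np.unique(faces) if len(faces) else np.array([], np.int64)
    remap = -np.ones(len(verts), np.int64)
    remap[used] = np.arange(len(used))
    new_verts = verts[used] if len(used) else verts
    new_faces = remap[faces] if len(faces) else faces.reshape(-1, 3)
    return TriMesh(new_verts, new_faces)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


def laplacian_smooth(mesh: TriMesh, iterations: int = 10, lam: float = 0.5) -> TriMesh:
    """Uniform-weight Laplacian smoothing.

    Each iteration moves every vertex by ``lam * (mean(1-ring) - vertex)``;
    vertices with no neighbours stay fixed.  Connectivity is untouched.
    """
    if iterations < 0:
        raise ParameterError("iterations must be >= 0")
    if not (0 < lam <= 1):
        raise ParameterError("lam must be in (0, 1]")
    out = mesh.copy()
    if iterations == 0 or out.n_vertices == 0:
        return out
    indptr, nbrs = out.vertex_adjacency()
    deg = np.diff(indptr).astype(float)
    movable = deg > 0
    verts = out.vertices
    for _ in range(iterations):
        sums = np.add.reduceat(
            verts[nbrs], indptr[:-1], axis=0
        ) if len(nbrs) else np.zeros_like(verts)
        # reduceat yields garbage rows where a slice is empty; mask them out
        means = np.where(movable[:, None], sums / np.maximum(deg, 1)[:, None], verts)
        verts = verts + lam * (means - verts)
    out.vertices = verts
    return out


# ---------------------------------------------------------------------------
# decimation — quadric edge collapse (Garland & Heckbert style)
# ---------------------------------------------------------------------------


def _face_quadrics(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    t = verts[faces]
    n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    n = n / np.where(norm > 0, norm, 1.0)
    d = -np.einsum("ij,ij->i", n, t[:, 0])
    p = np.concatenate([n, d[:, None]], axis=1)  # plane (a,b,c,d)
    return np.einsum("ij,ik->ijk", p, p)  # (M,4,4) fundamental quadrics


def _quadric_cost(Q: np.ndarray, va: np.ndarray, vb: np.ndarray) -> tuple[float, np.ndarray]:
    """Optimal collapse position for combined quadric Q and its cost."""
    A = Q[:3, :3]
    b = -Q[:3, 3]
    candidates = [(va + vb) / 2.0, va, vb]
    try:
        x = np.linalg.solve(A + 1e-12 * np.eye(3), b)
        if np.isfinite(x).all():
            candidates.insert(0, x)
    except np.linalg.LinAlgError:
        pass
    best_cost, best_x = np.inf, candidates[-1]
    for c in candidates:
        h = np.append(c, 1.0)
        cost = float(h @ Q @ h)
        if cost < best_cost:
            best_cost, best_x = cost, c
    return best_cost, best_x


def decimate(mesh: TriMesh, fraction: float) -> TriMesh:
    """Reduce the face count to ``ceil(fraction * M)`` by quadric edge collapse.

    Collapses are rejected when they would change topology (link condition)
    or produce degenerate faces, so closed meshes keep their genus.  The
    result is cleaned before returning.
    """
    if not (0 < fraction <= 1):
        raise ParameterError("fraction must be in (0, 1]")
    target = int(np.ceil(fraction * mesh.n_faces))
    if target < 4 and mesh.is_watertight():
        raise ParameterError(
            f"fraction {fraction} leaves {target} faces; a closed surface needs >= 4"
        )
    if fraction == 1.0 or mesh.n_faces <= target:
        return mesh.copy()

    verts = mesh.vertices.copy()
    faces = [list(f) for f in mesh.faces]
    alive_face = np.ones(len(faces), bool)
    quadrics = _face_quadrics(verts, mesh.faces)
    vq = np.zeros((len(verts), 4, 4))
    for fi, f in enumerate(mesh.faces):
        for v in f:
            vq[v] += quadrics[fi]

    # vertex -> set of incident alive faces
    vfaces: list[set[int]] = [set() for _ in range(len(verts))]
    for fi, f in enumerate(faces):
        for v in f:
            vfaces[v].add(fi)

    version = np.zeros(len(verts), np.int64)

    def neighbours(v: int) -> set[int]:
        out: set[int] = set()
        for fi in vfaces[v]:
            out.update(faces[fi])
        out.discard(v)
        return out

    heap: list[tuple[float, int, int, int, int, int, np.ndarray]] = []
    counter = 0

    def push_edge(a: int, b: int) -> None:
        nonlocal counter
        if a == b:
            return
        a, b = (a, b) if a < b else (b, a)
        cost, x = _quadric_cost(vq[a] + vq[b], verts[a], verts[b])
        counter += 1
        heapq.heappush(heap, (cost, a, b, int(version[a]), int(version[b]), counter, x))

    seen = set()
    for f in mesh.faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            if key not in seen:
                seen.add(key)
                push_edge(*key)
    del seen

    n_alive = int(alive_face.sum())
    while n_alive > target and heap:
        cost, a, b, va_ver, vb_ver, _, x = heapq.heappop(heap)
        if version[a] != va_ver or version[b] != vb_ver:
            continue  # stale entry
        if not (vfaces[a] and vfaces[b]):
            continue
        shared = vfaces[a] & vfaces[b]
        if not shared:
            continue
        # link condition: common neighbours must be exactly the shared faces' far corners
        common = neighbours(a) & neighbours(b)
        far = {v for fi in shared for v in faces[fi]} - {a, b}
        if common != far or len(shared) > 2:
            continue
        # simulate: reject if any surviving face would degenerate or flip badly
        ok = True
        moved = (vfaces[a] | vfaces[b]) - shared
        for fi in moved:
            tri = [x if v in (a, b) else verts[v] for v in faces[fi]]
            n_old = np.cross(
                verts[faces[fi][1]] - verts[faces[fi][0]],
                verts[faces[fi][2]] - verts[faces[fi][0]],
            )
            n_new = np.cross(tri[1] - tri[0], tri[2] - tri[0])
            area = np.linalg.norm(n_new)
            if area < 1e-14 or (n_old @ n_new) <= 0:
                ok = False
                break
        if not ok:
            continue
        # perform collapse: b -> a, a moves to x
        verts[a] = x
        vq[a] = vq[a] + vq[b]
        for fi in shared:
            alive_face[fi] = False
            for v in faces[fi]:
                vfaces[v].discard(fi)
            n_alive -= 1
        for fi in vfaces[b]:
            faces[fi] = [a if v == b else v for v in faces[fi]]
            vfaces[a].add(fi)
        vfaces[b] = set()
        version[a] += 1
        version[b] += 1
        for nb in neighbours(a):
            push_edge(a, nb)

    keep = [faces[fi] for fi in range(len(faces)) if alive_face[fi]]
    out = TriMesh(verts, np.array(keep, np.int64).reshape(-1, 3))
    return clean_mesh(out, merge_tol=0.0)
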