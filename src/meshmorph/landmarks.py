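"""Landmark I/O and the landmark-based analysis path.

Covers sparse anatomical landmark files in several dialects (MITK MPS XML,
MINC TAG, plain CSV/TXT, Amira landmarkAscii), least-squares similarity /
rigid alignment, Generalised Procrustes Analysis (GPA) and the Procrustes-
distance permutation test between two groups.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    ConsistencyError,
    DegenerateInputError,
    FormatError,
    ParameterError,
)
from .mesh import centroid_size

__all__ = [
    "LandmarkSet",
    "SimilarityTransform",
    "ProcrustesResult",
    "read_landmarks",
    "write_landmarks",
    "convert_landmarks",
    "fit_similarity",
    "gpa",
    "procrustes_permutation_test",
]


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class LandmarkSet:
    """Named 3-D landmark coordinates (mm) for one subject.

    Landmark order must be identical across subjects in a study; the
    names provide the correspondence.
    """

    names: list[str]
    coords: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float).reshape(-1, 3)
        if len(self.coords) < 1:
            raise ParameterError("LandmarkSet needs at least one landmark")
        if len(self.names) != len(self.coords):
            raise ConsistencyError("names and coords length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ConsistencyError("landmark names must be unique")

    @property
    def k(self) -> int:
        return len(self.coords)


@dataclass
class SimilarityTransform:
    """Rotation + translation (+ optional isotropic scale) in 3-D.

    Maps a point x to ``scale * rotation @ x + translation``; ``scale`` is 1
    for a rigid transform.
    """

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).ravel()
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ParameterError("rotation must be orthonormal with det +1")
        if not self.scale > 0:
            raise ParameterError("scale must be positive")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        return self.scale * pts @ self.rotation.T + self.translation


@dataclass
class ProcrustesResult:
    """Output of GPA: superimposed shapes, their mean and tangent coordinates."""

    aligned: list[np.ndarray]
    mean_shape: np.ndarray
    centroid_sizes: np.ndarray
    tangent_coords: np.ndarray  # (n_subjects, 3K) residuals from the mean
    n_iterations: int = 0


# ---------------------------------------------------------------------------
# file dialects
# ---------------------------------------------------------------------------


def _strip_comment_lines(text: str) -> list[str]:
    out = []
    for line in text.splitlines():
        s = line.strip()
        if not s or s.startswith(("#", "%", "//")):
            continue
        out.append(s)
    return out


def _read_csv_like(path: Path, sep: str | None) -> LandmarkSet:
    names, coords = [], []
    for i, line in enumerate(_strip_comment_lines(path.read_text())):
        parts = [p for p in (line.split(",") if sep == "," else line.split()) if p]
        if sep == "," :
            parts = [p.strip() for p in parts]
        try:
            xyz = [float(v) for v in parts[-3:]]
        except (ValueError, IndexError) as exc:
            if i == 0:
                continue  # tolerate a header row
            raise FormatError(f"{path}: cannot parse landmark row {line!r}") from exc
        coords.append(xyz)
        names.append(parts[0] if len(parts) > 3 else f"L{len(coords):03d}")
    if not coords:
        raise FormatError(f"{path}: no landmark rows found")
    return LandmarkSet(names, np.array(coords), subject_id=path.stem)


def _write_csv(lms: LandmarkSet, path: Path) -> None:
    lines = ["name,x,y,z"]
    for n, c in zip(lms.names, lms.coords):
        lines.append(f"{n},{float(c[0])!r},{float(c[1])!r},{float(c[2])!r}")
    path.write_text("\n".join(lines) + "\n")


def _write_txt(lms: LandmarkSet, path: Path) -> None:
    lines = [f"{n} {float(c[0])!r} {float(c[1])!r} {float(c[2])!r}"
             for n, c in zip(lms.names, lms.coords)]
    path.write_text("\n".join(lines) + "\n")


def _read_mps(path: Path) -> LandmarkSet:
    try:
        root = ET.fromstring(path.read_text())
    except ET.ParseError as exc:
        raise FormatError(f"{path}: malformed MPS XML: {exc}") from exc
    names, coords = [], []
    for p in root.iter("point"):
        try:
            pid = p.findtext("id", default=str(len(coords)))
            xyz = [float(p.findtext(ax)) for ax in ("x", "y", "z")]
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: point missing x/y/z") from exc
        names.append(f"P{pid}")
        coords.append(xyz)
    if not coords:
        raise FormatError(f"{path}: MPS file contains no <point> elements")
    return LandmarkSet(names, np.array(coords), subject_id=path.stem)


def _write_mps(lms: LandmarkSet, path: Path) -> None:
    lines = ["<?xml version=\"1.0\" encoding=\"UTF-8\"?>", "<point_set_file>",
             "  <point_set>", "    <time_series>", "      <time_series_id>0</time_series_id>"]
    for i, c in enumerate(lms.coords):
        lines += [
            "      <point>",
            f"        <id>{i}</id>",
            f"        <x>{float(c[0])!r}</x>",
            f"        <y>{float(c[1])!r}</y>",
            f"        <z>{float(c[2])!r}</z>",
            "      </point>",
        ]
    lines += ["    </time_series>", "  </point_set>", "</point_set_file>"]
    path.write_text("\n".join(lines) + "\n")


def _read_tag(path: Path) -> LandmarkSet:
    text = path.read_text()
    m = re.search(r"Points\s*=(.*?);", text, flags=re.S)
    if m is None:
        raise FormatError(f"{path}: TAG file has no 'Points =' block")
    names, coords = [], []
    for line in m.group(1).splitlines():
        s = line.strip()
        if not s:
            continue
        label = None
        lm = re.search(r'"([^"]*)"', s)
        if lm:
            label = lm.group(1)
            s = s[: lm.start()]
        nums = [float(v) for v in s.split()]
        if len(nums) < 3:
            raise FormatError(f"{path}: TAG point line with <3 coordinates: {line!r}")
        coords.append(nums[:3])  # first volume's triple
        names.append(label if label else f"L{len(coords):03d}")
    if not coords:
        raise FormatError(f"{path}: TAG file contains no points")
    return LandmarkSet(names, np.array(coords), subject_id=path.stem)


def _write_tag(lms: LandmarkSet, path: Path) -> None:
    lines = ["MNI Tag Point File", "Volumes = 1;", "", "Points ="]
    for n, c in zip(lms.names, lms.coords):
        lines.append(f" {float(c[0])!r} {float(c[1])!r} {float(c[2])!r} \"{n}\"")
    lines[-1] += ";"
    path.write_text("\n".join(lines) + "\n")


def _read_landmark_ascii(path: Path) -> LandmarkSet:
    lines = path.read_text().splitlines()
    n = None
    for line in lines:
        m = re.match(r"\s*define\s+Markers\s+(\d+)", line)
        if m:
            n = int(m.group(1))
            break
    data_start = None
    for i, line in enumerate(lines):
        if line.strip().startswith("@1"):
            data_start = i + 1
            break
    if data_start is None:
        raise FormatError(f"{path}: landmarkAscii file has no '@1' data section")
    coords = []
    for line in lines[data_start:]:
        s = line.strip()
        if not s:
            continue
        coords.append([float(v) for v in s.split()[:3]])
        if n is not None and len(coords) == n:
            break
    if not coords:
        raise FormatError(f"{path}: no coordinates after '@1'")
    names = [f"L{i + 1:03d}" for i in range(len(coords))]
    return LandmarkSet(names, np.array(coords), subject_id=path.stem)


def _write_landmark_ascii(lms: LandmarkSet, path: Path) -> None:
    lines = [
        "# AmiraMesh 3D ASCII 2.0",
        "",
        f"define Markers {lms.k}",
        "",
        "Parameters {",
        "    ContentType \"LandmarkSet\",",
        "    NumSets 1",
        "}",
        "",
        "Markers { float[3] Coordinates } @1",
        "",
        "@1",
    ]
    for c in lms.coords:
        lines.append(f"{float(c[0])!r} {float(c[1])!r} {float(c[2])!r}")
    path.write_text("\n".join(lines) + "\n")


_FMT_ALIASES = {
    "mps": "mps",
    "tag": "tag",
    "csv": "csv",
    "txt": "txt",
    "landmarkascii": "landmarkAscii",
}


def _infer_format(path: Path, format: str | None) -> str:
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FMT_ALIASES:
        raise FormatError(f"{path}: unknown landmark format {fmt!r}")
    return _FMT_ALIASES[fmt]


def read_landmarks(path: str | Path, format: str | None = None) -> LandmarkSet:
    """Read a landmark file; the dialect is inferred from the extension."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    fmt = _infer_format(path, format)
    if fmt == "mps":
        return _read_mps(path)
    if fmt == "tag":
        return _read_tag(path)
    if fmt == "csv":
        return _read_csv_like(path, sep=",")
    if fmt == "txt":
        return _read_csv_like(path, sep=None)
    return _read_landmark_ascii(path)


def write_landmarks(lms: LandmarkSet, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    {"mps": _write_mps, "tag": _write_tag, "csv": _write_csv,
     "txt": _write_txt, "landmarkAscii": _write_landmark_ascii}[fmt](lms, path)


def convert_landmarks(src: str | Path, dst: str | Path) -> LandmarkSet:
    """Translate a landmark file between dialects, preserving coordinates."""
    lms = read_landmarks(src)
    write_landmarks(lms, dst)
    return lms


# ---------------------------------------------------------------------------
# similarity alignment (Umeyama closed form)
# ---------------------------------------------------------------------------


def fit_similarity(
    source: LandmarkSet | np.ndarray,
    target: LandmarkSet | np.ndarray,
    allow_scale: bool = True,
) -> SimilarityTransform:
    """Least-squares similarity (or rigid) transform between matched points.

    Closed-form solution via the SVD of the cross-covariance matrix; at least
    four non-collinear matched landmarks are required for a well-posed 3-D
    alignment.  Reflections are never returned.
    """
    src = source.coords if isinstance(source, LandmarkSet) else np.asarray(source, float)
    dst = target.coords if isinstance(target, LandmarkSet) else np.asarray(target, float)
    if src.shape != dst.shape:
        raise ConsistencyError("source and target landmark counts differ")
    k = len(src)
    if k < 4:
        raise ParameterError("at least 4 matched landmarks are required")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    cov = xd.T @ xs / k
    U, S, Vt = np.linalg.svd(cov)
    if np.linalg.matrix_rank(xs, tol=1e-9 * max(1.0, np.abs(xs).max())) < 2:
        raise DegenerateInputError("landmarks are collinear; alignment is underdetermined")
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    if allow_scale:
        var_s = (xs**2).sum() / k
        scale = float(np.trace(np.diag(S) @ D) / var_s)
        if not scale > 0:
            raise DegenerateInputError("degenerate configuration: non-positive scale")
    else:
        scale = 1.0
    t = mu_d - scale * R @ mu_s
    return SimilarityTransform(R, t, scale)


# ---------------------------------------------------------------------------
# Generalised Procrustes Analysis
# ---------------------------------------------------------------------------


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (no reflection) minimising ||x @ R.T - target||."""
    U, _, Vt = np.linalg.svd(target.T @ x)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, 1.0, d]) @ Vt


def gpa(
    shapes: list[LandmarkSet] | list[np.ndarray],
    scale: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Generalised Procrustes superimposition of homologous configurations.

    Each shape is centred (and, when ``scale`` is on, scaled to unit centroid
    size), then iteratively rotated to the current mean until the mean stops
    changing (relative change < ``tol``).  Reflections are disallowed.
    Tangent coordinates are the flattened residuals from the mean shape.
    """
    arrs = [
        (s.coords if isinstance(s, LandmarkSet) else np.asarray(s, float)).reshape(-1, 3)
        for s in shapes
    ]
    if len(arrs) < 2:
        raise ParameterError("GPA needs at least two shapes")
    k = arrs[0].shape[0]
    if any(a.shape[0] != k for a in arrs):
        raise ConsistencyError("all shapes must have the same landmark count")

    sizes = np.array([centroid_size(a).centroid_size for a in arrs])
    if np.any(sizes == 0):
        raise DegenerateInputError("a shape has zero centroid size")
    X = [a - a.mean(axis=0) for a in arrs]
    if scale:
        X = [x / s for x, s in zip(X, sizes)]

    mean = X[0].copy()
    n_it = 0
    for n_it in range(1, max_iter + 1):
        X = [x @ _optimal_rotation(x, mean).T for x in X]
        new_mean = np.mean(X, axis=0)
        if scale:
            nm = np.sqrt((new_mean**2).sum())
            if nm > 0:
                new_mean = new_mean / nm
        change = np.linalg.norm(new_mean - mean) / max(np.linalg.norm(mean), 1e-300)
        mean = new_mean
        if change < tol:
            break
    tangent = np.stack([(x - mean).ravel() for x in X])
    return ProcrustesResult(X, mean, sizes, tangent, n_iterations=n_it)


def procrustes_permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation test on the distance between two group mean shapes.

    The statistic is the Euclidean distance between the group means in
    tangent space; group labels are permuted ``n_perm`` times and
    ``p = (#{perm >= observed} + 1) / (n_perm + 1)``.

    Returns ``(p_value, observed_distance)``.
    """
    A = np.asarray(group_a, float)
    B = np.asarray(group_b, float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ConsistencyError("groups must be 2-D with matching feature dimension")
    if len(A) < 2 or len(B) < 2:
        raise ParameterError("each group needs at least two subjects")
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    pooled = np.vstack([A, B])
    na = len(A)
    observed = float(np.linalg.norm(A.mean(axis=0) - B.mean(axis=0)))
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(len(pooled))
        d = np.linalg.norm(
            pooled[idx[:na]].mean(axis=0) - pooled[idx[na:]].mean(axis=0)
        )
        if d >= observed:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return p, observed
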