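"""Mesh containers, I/O, landmark handling, alignment and per-case geometric measures.

All coordinates are millimetres; volumes are reported in millilitres and
areas in mm². Meshes are triangulated surfaces; volume computations require
a watertight, consistently oriented mesh (divergence theorem).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

MM3_PER_ML = 1000.0

__all__ = [
    "SurfaceMesh",
    "LVGeometry",
    "CaseMetadata",
    "AnnulusFit",
    "RigidTransform",
    "read_surface",
    "write_surface",
    "read_landmarks",
    "write_landmarks",
    "enclosed_volume",
    "ef_sv",
    "sphericity_index",
    "closest_point_displacement",
    "wall_thickness",
    "closest_points_on_surface",
    "fit_annulus",
    "rigid_align",
]


@dataclass
class SurfaceMesh:
    """Triangulated, oriented surface with named landmarks.

    ``landmarks`` maps a name either to a single 3D point (shape ``(3,)``,
    e.g. ``apex``, ``rca_ostium``) or to an ordered point ring (shape
    ``(k, 3)``, e.g. ``mitral_annulus``, ``aortic_annulus``).
    """

    vertices: np.ndarray
    faces: np.ndarray
    landmarks: dict = field(default_factory=dict)
    manifold_warning: bool = False

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index exceeds vertex count")
        self.landmarks = {k: np.asarray(v, dtype=float) for k, v in self.landmarks.items()}

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def boundary_edge_count(self) -> int:
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int(np.sum(counts == 1))

    def is_watertight(self) -> bool:
        return self.boundary_edge_count() == 0 and self.as_trimesh().is_watertight

    def landmark_point(self, name: str) -> np.ndarray:
        if name not in self.landmarks:
            raise KeyError(f"landmark '{name}' missing")
        p = self.landmarks[name]
        if p.ndim != 1:
            raise ValueError(f"landmark '{name}' is a ring, not a point")
        return p

    def landmark_ring(self, name: str) -> np.ndarray:
        if name not in self.landmarks:
            raise KeyError(f"landmark ring '{name}' missing")
        r = self.landmarks[name]
        if r.ndim != 2:
            raise ValueError(f"landmark '{name}' is a point, not a ring")
        return r

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            self.faces.copy(),
            {k: v.copy() for k, v in self.landmarks.items()},
            self.manifold_warning,
        )


@dataclass
class CaseMetadata:
    """Clinical descriptors used for subcohort grouping.

    ``mr_grade`` is the mitral-regurgitation grade on a continuous 0–3
    scale; ``aneurysm_class`` is one of ``none | true | intermediate |
    hypokinetic`` (``unclassified`` is tolerated and excluded from the
    morphology subgrouping).
    """

    mr_grade: float
    aneurysm_class: str

    VALID_CLASSES = ("none", "true", "intermediate", "hypokinetic", "unclassified")

    def __post_init__(self):
        if not (0.0 <= self.mr_grade <= 3.0):
            raise ValueError(f"MR grade {self.mr_grade} outside [0, 3]")
        if self.aneurysm_class not in self.VALID_CLASSES:
            raise ValueError(f"unknown aneurysm class '{self.aneurysm_class}'")


@dataclass
class LVGeometry:
    """A single corresponded LV case: surfaces, contraction and wall thickness.

    ``displacement`` maps each end-diastolic vertex onto the end-systolic
    surface; ``thickness`` is the myocardial wall thickness sampled at each
    end-diastolic vertex.
    """

    ed_mesh: SurfaceMesh
    es_mesh: Optional[SurfaceMesh] = None
    myo_mesh: Optional[SurfaceMesh] = None
    displacement: Optional[np.ndarray] = None
    thickness: Optional[np.ndarray] = None
    metadata: Optional[CaseMetadata] = None

    def __post_init__(self):
        m = self.ed_mesh.n_vertices
        if self.displacement is not None:
            self.displacement = np.asarray(self.displacement, float).reshape(-1, 3)
            if len(self.displacement) != m:
                raise ValueError("displacement length != ED vertex count")
        if self.thickness is not None:
            self.thickness = np.asarray(self.thickness, float).ravel()
            if len(self.thickness) != m:
                raise ValueError("thickness length != ED vertex count")
            if np.any(self.thickness < 0):
                raise ValueError("negative wall thickness")


# ---------------------------------------------------------------------------
# I/O


def read_surface(path, fmt: Optional[str] = None) -> SurfaceMesh:
    """Read an STL / PLY / VTP triangulated surface.

    Landmarks are not part of surface files; attach them with
    :func:`read_landmarks`. A non-manifold mesh sets ``manifold_warning``
    and emits a warning instead of failing.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "vtp":
        from . import _vtkxml

        verts, faces, _ = _vtkxml.read_polydata(path)
    else:
        try:
            tm = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
        except Exception as exc:  # noqa: BLE001 - surface format zoo
            size = path.stat().st_size
            raise IOError(f"cannot parse {path} as {fmt} ({size} bytes): {exc}") from exc
        if not hasattr(tm, "faces") or len(tm.faces) == 0:
            raise IOError(f"cannot parse {path} as {fmt} "
                          f"({path.stat().st_size} bytes): no triangles found")
        if fmt == "stl":
            tm.merge_vertices()  # STL stores an unshared triangle soup
        verts, faces = np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64)
    mesh = SurfaceMesh(verts, faces)
    edges = np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if np.any(counts > 2):
        mesh.manifold_warning = True
        warnings.warn(f"{path.name}: mesh is not edge-manifold", stacklevel=2)
    return mesh


def write_surface(mesh: SurfaceMesh, path, fmt: Optional[str] = None,
                  point_data: Optional[dict] = None) -> None:
    """Write STL / PLY / VTP; VTP can carry per-vertex ``point_data`` arrays."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "vtp":
        from . import _vtkxml

        _vtkxml.write_polydata(path, mesh.vertices, mesh.faces, point_data or {})
    else:
        mesh.as_trimesh().export(str(path), file_type=fmt)


def read_landmarks(path) -> dict:
    """Load landmarks from JSON: ``{"points": {name: [x,y,z]}, "rings": {name: [[...]]}}``."""
    with open(path) as fh:
        raw = json.load(fh)
    out = {}
    for name, p in raw.get("points", {}).items():
        out[name] = np.asarray(p, float).reshape(3)
    for name, ring in raw.get("rings", {}).items():
        arr = np.asarray(ring, float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"ring '{name}' is not a (k,3) point list")
        out[name] = arr
    return out


def write_landmarks(landmarks: dict, path) -> None:
    points, rings = {}, {}
    for name, arr in landmarks.items():
        arr = np.asarray(arr, float)
        (points if arr.ndim == 1 else rings)[name] = arr.tolist()
    with open(path, "w") as fh:
        json.dump({"points": points, "rings": rings}, fh, indent=1)


# ---------------------------------------------------------------------------
# Measures


def enclosed_volume(mesh: SurfaceMesh) -> float:
    """Divergence-theorem volume of a watertight mesh in ml (orientation-invariant)."""
    nb = mesh.boundary_edge_count()
    if nb:
        raise ValueError(f"mesh is not watertight: {nb} boundary edges")
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    signed = np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0
    return abs(signed) / MM3_PER_ML


def ef_sv(edv: float, esv: float) -> tuple:
    """Stroke volume and ejection fraction from EDV/ESV (ml).

    Returns ``(sv, ef)`` with ``sv = edv - esv`` and ``ef = sv / edv``.
    """
    if edv <= 0:
        raise ValueError("EDV must be positive")
    if esv < 0 or esv > edv:
        raise ValueError(f"ESV={esv} outside [0, EDV={edv}]: not a contraction")
    sv = edv - esv
    return sv, sv / edv


def sphericity_index(mesh: SurfaceMesh) -> float:
    """LV roundness: cavity volume over the volume of the sphere whose
    diameter equals the apex-to-mitral-annulus-centroid long-axis length.

    Equals 1 for a sphere whose diameter is its long axis and decreases
    with elongation.
    """
    apex = mesh.landmark_point("apex")
    annulus = mesh.landmark_ring("mitral_annulus")
    long_axis = float(np.linalg.norm(apex - annulus.mean(axis=0)))
    if long_axis <= 0:
        raise ValueError("degenerate long axis")
    v_sphere = np.pi / 6.0 * long_axis**3 / MM3_PER_ML
    return enclosed_volume(mesh) / v_sphere


# ---------------------------------------------------------------------------
# Closest-point machinery (KD-tree candidate search + exact point-triangle)


def _point_triangle_closest(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest points on triangles ``tri`` (k,3,3) to a single point ``p``."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p[None, :] - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p[None, :] - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p[None, :] - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(a), bool)

    reg = (d1 <= 0) & (d2 <= 0)
    out[reg], done[reg] = a[reg], True
    reg = (~done) & (d3 >= 0) & (d4 <= d3)
    out[reg], done[reg] = b[reg], True
    vc = d1 * d4 - d3 * d2
    reg = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    out[reg], done[reg] = a[reg] + t[reg, None] * ab[reg], True
    reg = (~done) & (d6 >= 0) & (d5 <= d6)
    out[reg], done[reg] = c[reg], True
    vb = d5 * d2 - d1 * d6
    reg = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    out[reg], done[reg] = a[reg] + t[reg, None] * ac[reg], True
    va = d3 * d6 - d5 * d4
    reg = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    out[reg], done[reg] = b[reg] + t[reg, None] * (c[reg] - b[reg]), True
    reg = ~done
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 1 / 3)
        w = np.where(denom != 0, vc / denom, 1 / 3)
    out[reg] = a[reg] + v[reg, None] * ab[reg] + w[reg, None] * ac[reg]
    return out


def closest_points_on_surface(mesh: SurfaceMesh, points: np.ndarray):
    """Exact closest point on ``mesh`` for each query point.

    Candidate triangles come from a KD-tree over triangle centroids; the
    search radius per query is the nearest-vertex distance plus the largest
    centroid-to-corner extent, which guarantees the true nearest triangle is
    among the candidates. Ties are broken by the smallest triangle index.

    Returns ``(closest (n,3), distance (n,), triangle_index (n,))``.
    """
    points = np.asarray(points, float).reshape(-1, 3)
    if mesh.faces.size == 0:
        raise ValueError("empty mesh")
    tri = mesh.vertices[mesh.faces]
    centroids = tri.mean(axis=1)
    spread = np.linalg.norm(tri - centroids[:, None, :], axis=2).max()
    vtree = cKDTree(mesh.vertices)
    ctree = cKDTree(centroids)
    d_vert, _ = vtree.query(points)

    closest = np.empty_like(points)
    dist = np.empty(len(points))
    tri_idx = np.empty(len(points), np.int64)
    for i, p in enumerate(points):
        cand = ctree.query_ball_point(p, d_vert[i] + spread + 1e-9)
        cand = np.asarray(cand if cand else range(len(tri)), np.int64)
        cand.sort()
        cps = _point_triangle_closest(p, tri[cand])
        dd = np.linalg.norm(cps - p[None, :], axis=1)
        j = int(np.argmin(dd))  # argmin returns first minimum -> smallest index
        closest[i], dist[i], tri_idx[i] = cps[j], dd[j], cand[j]
    return closest, dist, tri_idx


def closest_point_displacement(ed: SurfaceMesh, es: SurfaceMesh) -> np.ndarray:
    """Per-ED-vertex vector to the closest point on the ES surface (mm)."""
    if ed.n_vertices == 0 or es.n_vertices == 0:
        raise ValueError("empty mesh")
    cp, _, _ = closest_points_on_surface(es, ed.vertices)
    return cp - ed.vertices


def wall_thickness(ed: SurfaceMesh, myo: SurfaceMesh) -> np.ndarray:
    """Unsigned closest-point distance from each ED vertex to the epicardium (mm)."""
    if ed.n_vertices == 0 or myo.n_vertices == 0:
        raise ValueError("empty mesh")
    _, dist, _ = closest_points_on_surface(myo, ed.vertices)
    return dist


# ---------------------------------------------------------------------------
# Annulus fitting


@dataclass
class AnnulusFit:
    """Planar annulus fit: an ellipse (aortic) or a cardioid (mitral).

    Areas use the closed forms π·a·b (ellipse) and (3/2)·π·a² (cardioid,
    r = a(1+cos θ)).
    """

    kind: str
    center: np.ndarray
    plane_normal: np.ndarray
    params: dict
    area: float


def _best_fit_plane(points: np.ndarray):
    centroid = points.mean(axis=0)
    u, s, vt = np.linalg.svd(points - centroid)
    if s[1] < 1e-9 * max(s[0], 1e-30):
        raise ValueError("annulus points are collinear")
    return centroid, vt[0], vt[1], vt[2]  # origin, in-plane e1/e2, normal


def _fit_ellipse_2d(x: np.ndarray, y: np.ndarray):
    """Direct algebraic ellipse fit (Fitzgibbon); returns center, axes, angle."""
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1, S2, S3 = D1.T @ D1, D1.T @ D2, D2.T @ D2
    T = -np.linalg.solve(S3, S2.T)
    M = S1 + S2 @ T
    C = np.array([[0, 0, 2.0], [0, -1.0, 0], [2.0, 0, 0]])
    M = np.linalg.solve(C, M)
    w, v = np.linalg.eig(M)
    cond = 4 * v[0] * v[2] - v[1] ** 2
    a1 = v[:, np.isreal(w) & (cond > 0)].real
    if a1.size == 0:
        raise ValueError("ellipse fit failed (degenerate points)")
    A, B, Cc = a1[:, 0]
    D, E, F = T @ a1[:, 0]
    if A + Cc < 0:  # eigenvector sign is arbitrary; make the quadratic part PD
        A, B, Cc, D, E, F = -A, -B, -Cc, -D, -E, -F
    # conic matrix form: axes from the eigenvalues of the quadratic part
    Q = np.array([[A, B / 2, D / 2], [B / 2, Cc, E / 2], [D / 2, E / 2, F]])
    M = Q[:2, :2]
    detM = np.linalg.det(M)
    if detM <= 0:
        raise ValueError("ellipse fit degenerate (not an ellipse)")
    center2 = np.linalg.solve(M, [-D / 2, -E / 2])
    lam, vecs = np.linalg.eigh(M)
    k = -np.linalg.det(Q) / detM
    if k <= 0:
        raise ValueError("ellipse fit degenerate (imaginary axes)")
    axes = np.sqrt(k / lam)  # semi-axes along the eigenvectors
    order = np.argsort(-axes)
    major, minor = axes[order]
    vmaj = vecs[:, order[0]]
    theta = float(np.arctan2(vmaj[1], vmaj[0]))
    return (center2[0], center2[1]), float(major), float(minor), theta


def _fit_cardioid_2d(x: np.ndarray, y: np.ndarray):
    """Least-squares cardioid r = a(1+cos(θ-θ0)) about a free pole."""

    def residual(q):
        px, py, a, th0 = q
        dx, dy = x - px, y - py
        r = np.hypot(dx, dy)
        th = np.arctan2(dy, dx)
        return r - a * (1 + np.cos(th - th0))

    cx, cy = x.mean(), y.mean()
    r0 = np.hypot(x - cx, y - cy).mean()
    best = None
    for th0 in np.linspace(0, 2 * np.pi, 8, endpoint=False):
        # pole sits opposite the lobe: offset initial pole against th0
        q0 = [cx - 0.5 * r0 * np.cos(th0), cy - 0.5 * r0 * np.sin(th0), r0, th0]
        sol = least_squares(residual, q0, method="lm", max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
    px, py, a, th0 = best.x
    return (px, py), abs(a), th0 % (2 * np.pi)


def fit_annulus(points: np.ndarray, kind: str) -> AnnulusFit:
    """Fit an annulus landmark ring with an ellipse or a cardioid.

    The fit is performed in the ring's best-fit plane (total least squares);
    the area comes from the closed-form expression of the fitted curve.
    """
    points = np.asarray(points, float).reshape(-1, 3)
    min_pts = 6 if kind == "ellipse" else 8
    if len(points) < min_pts:
        raise ValueError(f"{kind} fit needs >= {min_pts} points, got {len(points)}")
    origin, e1, e2, normal = _best_fit_plane(points)
    rel = points - origin
    x, y = rel @ e1, rel @ e2
    if kind == "ellipse":
        (cx, cy), a, b, theta = _fit_ellipse_2d(x, y)
        center = origin + cx * e1 + cy * e2
        return AnnulusFit("ellipse", center, normal,
                          {"a": float(a), "b": float(b), "angle": float(theta)},
                          float(np.pi * a * b))
    if kind == "cardioid":
        (px, py), a, th0 = _fit_cardioid_2d(x, y)
        center = origin + px * e1 + py * e2
        return AnnulusFit("cardioid", center, normal,
                          {"a": float(a), "angle": float(th0)},
                          float(1.5 * np.pi * a * a))
    raise ValueError(f"unknown annulus kind '{kind}'")


# ---------------------------------------------------------------------------
# Rigid alignment


@dataclass
class RigidTransform:
    """Rotation + translation (no scaling): ``x -> R @ x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    @property
    def scale(self) -> float:
        return 1.0

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, float) @ self.rotation.T + self.translation

    def apply_vectors(self, vecs: np.ndarray) -> np.ndarray:
        return np.asarray(vecs, float) @ self.rotation.T

    def compose_identity_check(self) -> float:
        return float(np.abs(self.rotation - np.eye(3)).max() + np.abs(self.translation).max())


ALIGNMENT_LANDMARKS = ("apex", "rca_ostium", "mitral_centroid", "aortic_centroid")


def _alignment_points(case: LVGeometry) -> np.ndarray:
    m = case.ed_mesh
    return np.array([
        m.landmark_point("apex"),
        m.landmark_point("rca_ostium"),
        m.landmark_ring("mitral_annulus").mean(axis=0),
        m.landmark_ring("aortic_annulus").mean(axis=0),
    ])


def rigid_align(case: LVGeometry, reference: LVGeometry, apply: bool = True) -> RigidTransform:
    """Landmark Procrustes alignment of ``case`` onto ``reference`` (no scaling).

    Uses apex, RCA ostium and the two annulus-ring centroids; the Kabsch
    rotation is deterministic. With ``apply=True`` the transform is applied
    in place to all of the case's meshes, landmarks and displacement vectors.
    """
    src, dst = _alignment_points(case), _alignment_points(reference)
    src_c, dst_c = src.mean(axis=0), dst.mean(axis=0)
    A, B = src - src_c, dst - dst_c
    if np.linalg.matrix_rank(A, tol=1e-8 * max(1.0, np.abs(A).max())) < 2:
        raise ValueError("degenerate (collinear) landmark configuration")
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = dst_c - R @ src_c
    tf = RigidTransform(R, t)
    if apply:
        for mesh in (case.ed_mesh, case.es_mesh, case.myo_mesh):
            if mesh is None:
                continue
            mesh.vertices = tf.apply_points(mesh.vertices)
            for k, v in mesh.landmarks.items():
                mesh.landmarks[k] = tf.apply_points(v) if v.ndim == 2 else tf.apply_points(v[None])[0]
        if case.displacement is not None:
            case.displacement = tf.apply_vectors(case.displacement)
    return tf
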