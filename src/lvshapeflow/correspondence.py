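"""Point correspondence via per-patch disc parameterization.

Each AHA segment of the endocardial surface is a topological disc. The patch
is flattened to the unit disc — boundary mapped to the circle by cumulative
arc length from an anatomically canonical corner, interior by mean-value
coordinates (a convex-combination Laplacian, robust on the convex-ish
patches that arise here) — and resampled on a fixed polar template grid.
Because every case is sampled on the same template, all cases share the
vertex count and patch-wise ordering required by the shape model.

The resampled surface is a patchwork: neighbouring patches duplicate their
border samples rather than sharing vertices, which is exactly what the
feature matrix needs but makes the result unsuitable for enclosed-volume
computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import spsolve

from .geometry import SurfaceMesh
from .segments import SegmentMap


class PatchTopologyError(ValueError):
    """Raised when a segment patch is not a topological disc."""


@dataclass
class PatchTemplate:
    """Fixed polar sampling grid applied to every flattened patch.

    ``n_radial`` rings at radii (k+1)/n_radial (outermost on the boundary
    circle) with ``n_angular`` samples each, plus the disc center.
    """

    n_radial: int = 7
    n_angular: int = 24
    n_patches: int = 17

    @property
    def points_per_patch(self) -> int:
        return self.n_radial * self.n_angular + 1

    @property
    def total_points(self) -> int:
        return self.n_patches * self.points_per_patch

    def disc_points(self) -> np.ndarray:
        r = (np.arange(self.n_radial) + 1) / self.n_radial
        th = 2 * np.pi * np.arange(self.n_angular) / self.n_angular
        rr, tt = np.meshgrid(r, th, indexing="ij")
        pts = np.column_stack([(rr * np.cos(tt)).ravel(), (rr * np.sin(tt)).ravel()])
        return np.vstack([[0.0, 0.0], pts])  # center first

    def patch_faces(self) -> np.ndarray:
        """Triangulation of the polar grid in local indices (center = 0)."""
        na, nr = self.n_angular, self.n_radial

        def idx(k, l):
            return 1 + k * na + (l % na)

        faces = []
        for l in range(na):  # fan around the center
            faces.append([0, idx(0, l), idx(0, l + 1)])
        for k in range(nr - 1):
            for l in range(na):
                a, b = idx(k, l), idx(k, l + 1)
                c, d = idx(k + 1, l), idx(k + 1, l + 1)
                faces.append([a, c, d])
                faces.append([a, d, b])
        return np.asarray(faces, np.int64)


# ---------------------------------------------------------------------------


def _patch_submesh(mesh: SurfaceMesh, labels: np.ndarray, seg: int):
    vmask = labels == seg
    if not vmask.any():
        raise PatchTopologyError(f"segment {seg}: empty patch")
    fmask = vmask[mesh.faces].all(axis=1)
    faces = mesh.faces[fmask]
    used = np.unique(faces)
    local = -np.ones(mesh.n_vertices, np.int64)
    local[used] = np.arange(len(used))
    return used, local[faces]


def _boundary_loop(faces: np.ndarray, n_verts: int, seg: int) -> np.ndarray:
    """Single oriented boundary loop of a disc patch (local vertex indices)."""
    edges = faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    key = np.sort(edges, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = edges[counts[inv] == 1]  # directed as induced by face orientation
    if len(boundary) == 0:
        raise PatchTopologyError(f"segment {seg}: patch has no boundary (closed surface)")
    nxt = {int(a): int(b) for a, b in boundary}
    if len(nxt) != len(boundary):
        raise PatchTopologyError(f"segment {seg}: non-manifold patch boundary")
    start = int(boundary[0, 0])
    loop, cur = [start], nxt[start]
    while cur != start:
        loop.append(cur)
        cur = nxt.get(cur)
        if cur is None or len(loop) > len(boundary):
            raise PatchTopologyError(f"segment {seg}: broken boundary loop")
    if len(loop) != len(boundary):
        raise PatchTopologyError(
            f"segment {seg}: patch is not a disc (multiple boundary loops — hole or handle)")
    # Euler characteristic check: V - E + F must be 1 for a disc
    n_edges = len(np.unique(key, axis=0))
    if n_verts - n_edges + len(faces) != 1:
        raise PatchTopologyError(f"segment {seg}: patch is not a disc (Euler check failed)")
    return np.asarray(loop, np.int64)


def _mean_value_weights(verts: np.ndarray, faces: np.ndarray) -> csr_matrix:
    """Sparse symmetric-pattern matrix W with mean-value weights w_ij."""
    n = len(verts)
    rows, cols, vals = [], [], []
    for c in range(3):
        i = faces[:, c]
        j = faces[:, (c + 1) % 3]
        k = faces[:, (c + 2) % 3]
        e1 = verts[j] - verts[i]
        e2 = verts[k] - verts[i]
        n1 = np.linalg.norm(e1, axis=1)
        n2 = np.linalg.norm(e2, axis=1)
        cosang = np.clip(np.einsum("ij,ij->i", e1, e2) / np.maximum(n1 * n2, 1e-30), -1, 1)
        t = np.tan(0.5 * np.arccos(cosang))
        # the angle at i feeds the mean-value weight of both edges (i,j), (i,k)
        rows.extend([i, i])
        cols.extend([j, k])
        vals.extend([t / np.maximum(n1, 1e-30), t / np.maximum(n2, 1e-30)])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return csr_matrix((vals, (rows, cols)), shape=(n, n))


def _flatten_patch(verts: np.ndarray, faces: np.ndarray, loop: np.ndarray,
                   anchor_local: int) -> np.ndarray:
    """Map a disc patch to the unit disc; returns (n,2) parameter coordinates."""
    # rotate the loop so it starts at the canonical anchor
    pos = int(np.where(loop == anchor_local)[0][0])
    loop = np.roll(loop, -pos)
    seglen = np.linalg.norm(verts[np.roll(loop, -1)] - verts[loop], axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])[:-1]
    theta = 2 * np.pi * arc / max(arc[-1] + seglen[-1], 1e-30)
    uv = np.zeros((len(verts), 2))
    uv[loop, 0] = np.cos(theta)
    uv[loop, 1] = np.sin(theta)

    interior = np.setdiff1d(np.arange(len(verts)), loop)
    if len(interior):
        W = _mean_value_weights(verts, faces)
        diag = np.asarray(W.sum(axis=1)).ravel()
        from scipy.sparse import diags

        A = (diags(diag) - W).tocsr()
        Aii = A[interior][:, interior]
        Aib = A[interior][:, loop]
        rhs = -Aib @ uv[loop]
        uv[interior] = np.column_stack([
            spsolve(Aii, rhs[:, 0]), spsolve(Aii, rhs[:, 1])
        ])
    return uv


def _barycentric_sample(uv: np.ndarray, faces: np.ndarray, verts3d: np.ndarray,
                        targets: np.ndarray):
    """Locate 2-D targets in the flattened triangulation; map back to 3-D.

    Returns the sampled 3-D points and the (face index, barycentric) pairs so
    per-vertex fields can be carried along with identical weights.
    """
    from matplotlib.tri import Triangulation, TrapezoidMapTriFinder

    tri = Triangulation(uv[:, 0], uv[:, 1], faces)
    finder = TrapezoidMapTriFinder(tri)
    fidx = finder(targets[:, 0], targets[:, 1])
    out = np.empty((len(targets), 3))
    bary_info = []
    for i, (pt, fi) in enumerate(zip(targets, fidx)):
        if fi < 0:  # shrink toward the center to dodge boundary round-off
            for shrink in (0.999, 0.99, 0.95):
                cand = int(finder(np.array([pt[0] * shrink]),
                                  np.array([pt[1] * shrink]))[0])
                if cand >= 0:
                    fi, pt = cand, pt * shrink
                    break
        if fi < 0:  # last resort: nearest flattened vertex
            vi = int(np.argmin(np.linalg.norm(uv - pt[None], axis=1)))
            out[i] = verts3d[vi]
            bary_info.append((None, vi))
            continue
        f = faces[fi]
        T = np.column_stack([uv[f[0]] - uv[f[2]], uv[f[1]] - uv[f[2]]])
        try:
            lam = np.linalg.solve(T, pt - uv[f[2]])
        except np.linalg.LinAlgError:
            lam = np.array([1 / 3, 1 / 3])
        bary = np.array([lam[0], lam[1], 1 - lam.sum()])
        bary = np.clip(bary, 0.0, 1.0)
        bary /= bary.sum()
        out[i] = bary @ verts3d[f]
        bary_info.append((f, bary))
    return out, bary_info


def _canonical_anchor(loop: np.ndarray, verts: np.ndarray, segmap: SegmentMap,
                      seg: int) -> int:
    """Boundary vertex closest to the patch's canonical (basal, sector-start)
    corner in normalized (height, azimuth) coordinates."""
    rel = verts - segmap.base_point
    height = np.linalg.norm(segmap.apex - segmap.base_point)
    h = np.clip(rel @ segmap.axis / height, 0.0, 1.0)
    e2 = np.cross(segmap.axis, segmap.azimuth_ref)
    az = np.degrees(np.arctan2(rel @ e2, rel @ segmap.azimuth_ref)) % 360.0
    if seg == 17:
        h0, az0 = 1.0 - segmap.cap_fraction, 0.0
    elif seg >= 13:
        h0, az0 = 2.0 / 3.0, (345.0 + 90.0 * (seg - 13)) % 360.0
    elif seg >= 7:
        h0, az0 = 1.0 / 3.0, 60.0 * (seg - 7)
    else:
        h0, az0 = 0.0, 60.0 * (seg - 1)
    dh = np.abs(h[loop] - h0) * 3.0           # slab heights ~1/3
    daz = np.minimum((az[loop] - az0) % 360.0, (az0 - az[loop]) % 360.0) / 60.0
    return int(loop[np.argmin(dh + daz)])


def correspond(mesh: SurfaceMesh, segmap: SegmentMap,
               template: Optional[PatchTemplate] = None,
               fields: Optional[dict] = None):
    """Resample a labeled surface onto the fixed per-patch polar template.

    Returns ``(resampled SurfaceMesh, resampled fields dict)``. Vertex
    ordering is patch-major (segments 1..17), each patch ordered center
    first, then rings inside-out; scalar or (n,3) vector ``fields`` given
    per source vertex are carried through the same barycentric weights.
    """
    template = template or PatchTemplate()
    fields = fields or {}
    disc = template.disc_points()
    all_pts, all_faces = [], []
    out_fields = {k: [] for k in fields}
    offset = 0
    pf = template.patch_faces()
    for seg in range(1, template.n_patches + 1):
        used, faces_local = _patch_submesh(mesh, segmap.labels, seg)
        verts = mesh.vertices[used]
        loop = _boundary_loop(faces_local, len(used), seg)
        anchor = _canonical_anchor(loop, verts, segmap, seg)
        uv = _flatten_patch(verts, faces_local, loop, anchor)
        pts3d, bary = _barycentric_sample(uv, faces_local, verts, disc)
        all_pts.append(pts3d)
        all_faces.append(pf + offset)
        offset += template.points_per_patch
        for name, arr in fields.items():
            arr = np.asarray(arr, float)
            sub = arr[used]
            vals = np.empty((len(disc),) + sub.shape[1:])
            for i, (f, b) in enumerate(bary):
                vals[i] = sub[b] if f is None else np.tensordot(b, sub[f], axes=1)
            out_fields[name].append(vals)
    res = SurfaceMesh(np.vstack(all_pts), np.vstack(all_faces),
                      {k: v.copy() for k, v in mesh.landmarks.items()})
    return res, {k: np.concatenate(v) for k, v in out_fields.items()}
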