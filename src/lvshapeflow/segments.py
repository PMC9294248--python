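"""AHA 17-segment parcellation of the LV endocardial surface.

The parcellation is fully landmark-driven: a base plane fitted to the two
annulus rings, a long axis from the base-plane centroid to the apex, and the
RCA–apex plane fixing the azimuthal origin. Slab borders sit at 1/3 and 2/3
of the axial height; the basal and mid slabs carry six 60° sectors each, the
apical slab four 90° sectors, and the apical cap (segment 17) covers the
most apical fraction of the axial height.

Labeling convention (the standard fixes only the RCA–apex plane, not the
origin): the RCA–apex plane is the border between segment 1 (anterior) and
segment 2 (anteroseptal); sectors advance counterclockwise viewed from the
base; segment 13 (apical anterior) is centered on the anterior azimuth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SurfaceMesh

APEX_CAP_FRACTION = 0.10  # axial-height fraction of segment 17; configurable


@dataclass
class SegmentMap:
    """Per-vertex AHA labels plus the frame that produced them."""

    labels: np.ndarray           # per-vertex int in 1..17
    apex: np.ndarray             # mm
    base_point: np.ndarray       # base-plane centroid, mm
    axis: np.ndarray             # unit vector base -> apex
    azimuth_ref: np.ndarray      # unit vector, anterior direction in base plane
    cap_fraction: float

    @property
    def segment_ids(self):
        return np.arange(1, 18)

    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=18)[1:]


def _frame_from_landmarks(mesh: SurfaceMesh, cap_fraction: float):
    apex = mesh.landmark_point("apex")
    rca = mesh.landmark_point("rca_ostium")
    ring_pts = np.vstack([mesh.landmark_ring("mitral_annulus"),
                          mesh.landmark_ring("aortic_annulus")])
    base_point = ring_pts.mean(axis=0)
    axis = apex - base_point
    height = np.linalg.norm(axis)
    if height <= 1e-12:
        raise ValueError("zero-length long axis (apex coincides with base centroid)")
    axis = axis / height
    ref = rca - base_point
    ref = ref - (ref @ axis) * axis
    nref = np.linalg.norm(ref)
    if nref <= 1e-12:
        raise ValueError("RCA ostium lies on the long axis; azimuth undefined")
    ref = ref / nref
    e2 = np.cross(axis, ref)
    return apex, base_point, axis, ref, e2, height


def segment_of(h_frac: float, azimuth_deg: float, cap_fraction: float = APEX_CAP_FRACTION) -> int:
    """AHA label for one vertex given its axial-height fraction (0 = base,
    1 = apex) and azimuth in degrees from the RCA–apex plane (counter-
    clockwise viewed from the base). Used both by :func:`assign_segments`
    and as an independent scalar re-derivation in tests."""
    az = azimuth_deg % 360.0
    if h_frac >= 1.0 - cap_fraction:
        return 17
    if h_frac >= 2.0 / 3.0:
        return 13 + int(((az + 15.0) % 360.0) // 90.0)
    sector = int(az // 60.0)
    if h_frac >= 1.0 / 3.0:
        return 7 + sector
    return 1 + sector


def assign_segments(mesh: SurfaceMesh, cap_fraction: float = APEX_CAP_FRACTION) -> SegmentMap:
    """Label every vertex with its AHA 17-segment id.

    Axial height is measured along the straight base-to-apex axis (not arc
    length) and clipped to [0, 1] so basal tissue right at or above the
    annulus plane stays in the basal slab.
    """
    apex, base_point, axis, ref, e2, height = _frame_from_landmarks(mesh, cap_fraction)
    rel = mesh.vertices - base_point
    h = np.clip((rel @ axis) / height, 0.0, 1.0)
    az = np.degrees(np.arctan2(rel @ e2, rel @ ref)) % 360.0

    labels = np.empty(mesh.n_vertices, np.int64)
    cap = h >= 1.0 - cap_fraction
    apical = (~cap) & (h >= 2.0 / 3.0)
    mid = (~cap) & (~apical) & (h >= 1.0 / 3.0)
    basal = ~(cap | apical | mid)
    labels[cap] = 17
    labels[apical] = 13 + (((az[apical] + 15.0) % 360.0) // 90.0).astype(np.int64)
    labels[mid] = 7 + (az[mid] // 60.0).astype(np.int64)
    labels[basal] = 1 + (az[basal] // 60.0).astype(np.int64)
    return SegmentMap(labels, apex, base_point, axis, ref, cap_fraction)


def segment_aggregate(segmap: SegmentMap, field: np.ndarray) -> np.ndarray:
    """Arithmetic mean of a per-vertex field per segment (17 values).

    Empty segments yield NaN, never a silent zero.
    """
    field = np.asarray(field, float).ravel()
    if len(field) != len(segmap.labels):
        raise ValueError(f"field length {len(field)} != vertex count {len(segmap.labels)}")
    out = np.full(17, np.nan)
    for k in range(1, 18):
        mask = segmap.labels == k
        if mask.any():
            out[k - 1] = field[mask].mean()
    return out


def bullseye_plot(values: np.ndarray, ax=None, cmap: str = "viridis"):
    """Minimal polar bull's-eye rendering of 17 per-segment values."""
    import matplotlib.pyplot as plt

    values = np.asarray(values, float).ravel()
    if len(values) != 17:
        raise ValueError("need 17 values")
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    vmin, vmax = np.nanmin(values), np.nanmax(values)
    norm = plt.Normalize(vmin, vmax if vmax > vmin else vmin + 1)
    cm = plt.get_cmap(cmap)
    rings = [(1, 6, 60.0, 0.75, 1.0, 0.0), (7, 6, 60.0, 0.5, 0.75, 0.0),
             (13, 4, 90.0, 0.25, 0.5, -45.0)]
    for first, n, width, r0, r1, offset in rings:
        for i in range(n):
            th0 = np.radians(offset + i * width)
            th = np.linspace(th0, th0 + np.radians(width), 16)
            v = values[first - 1 + i]
            ax.fill_between(th, r0, r1, color=cm(norm(v)) if np.isfinite(v) else "0.8")
    ax.fill_between(np.linspace(0, 2 * np.pi, 64), 0, 0.25,
                    color=cm(norm(values[16])) if np.isfinite(values[16]) else "0.8")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
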