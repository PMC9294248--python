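"""Synthetic LV cohorts, contraction fields and analytic flow fields.

Everything downstream of image segmentation is testable without patient
data: this module produces watertight, landmark-equipped LV-like surfaces
with controllable sphericity, apical-anterior aneurysm bulges, wall
thinning and segment-wise hypokinesis; cohorts with planted orthogonal
variation modes for shape-model recovery studies; analytic velocity fields
for the energetic markers; and closed-form well-mixed washout series.

The endocardium is a truncated prolate spheroid sampled on a fixed
(rings × azimuth) grid and closed by an apex vertex and a flat basal lid,
so every generated case shares vertex count and ordering — the cohort is
corresponded by construction and shape-model tests isolate PCA behavior
from correspondence error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .geometry import CaseMetadata, LVGeometry, SurfaceMesh, enclosed_volume
from .hemo import FieldSnapshot, VoxelGrid
from .motion import volume_polynomial
from .segments import assign_segments

__all__ = [
    "LVGenParams",
    "make_lv",
    "make_cohort",
    "CohortSpec",
    "make_flow_snapshot",
    "make_wellmixed_series",
    "stirred_box_velocity",
]

# aneurysm morphology presets: (bulge amplitude mm, axial sharpness, thinning)
_ANEURYSM_PRESETS = {
    "none": (0.0, 0.18, 0.0),
    "true": (9.0, 0.09, 0.5),          # narrow, deep -> two curvature sign changes
    "intermediate": (14.0, 0.10, 0.4),  # apex-merged flare -> one sign change
    "hypokinetic": (0.0, 0.18, 0.3),   # no bulge; contraction deficit instead
}


@dataclass
class LVGenParams:
    """Controls for one synthetic LV case.

    ``sphericity`` in (0, 1] widens the short axis relative to the long
    axis; ``hypokinesis`` maps AHA segment ids to motion multipliers in
    [0, 1] (unlisted segments move fully). The default long axis, wall
    thickness and EF sit in the range reported for dilated ischemic
    ventricles (EDV of a few hundred ml, EF ~0.25, ~8 mm walls).
    """

    long_axis: float = 100.0         # mm, apex to base
    sphericity: float = 0.65         # (0, 1]
    wall_thickness: float = 8.0      # mm
    aneurysm: str = "none"
    bulge_amplitude: Optional[float] = None   # mm; None -> class preset
    bulge_sharpness: Optional[float] = None   # axial Gaussian width (u units)
    thinning: Optional[float] = None          # fraction of thickness lost in bulge
    hypokinesis: dict = field(default_factory=dict)
    target_ef: float = 0.25
    mr_grade: float = 1.0
    n_rings: int = 48
    n_azimuth: int = 52
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.sphericity <= 1.0):
            raise ValueError("sphericity must be in (0, 1]")
        if self.aneurysm not in _ANEURYSM_PRESETS:
            raise ValueError(f"unknown aneurysm class '{self.aneurysm}'")
        if not (0.0 < self.target_ef < 1.0):
            raise ValueError("target EF must be in (0, 1)")
        preset = _ANEURYSM_PRESETS[self.aneurysm]
        if self.bulge_amplitude is None:
            self.bulge_amplitude = preset[0]
        if self.bulge_sharpness is None:
            self.bulge_sharpness = preset[1]
        if self.thinning is None:
            self.thinning = preset[2]


# bulge location: apical-anterior, left of the apex along the anterior wall
_BULGE_U0 = 0.78       # axial position (0 base, 1 apex)
_BULGE_PHI0 = 0.9      # rad, anterior-lateral azimuth
_BULGE_PHI_WIDTH = 0.7  # rad


def _bulge_profile(u: np.ndarray, phi: np.ndarray, params: LVGenParams) -> np.ndarray:
    """Smooth bump in (axial, azimuthal) coordinates, peak value 1.

    The "true" sac sits left of the apex with a neck on both sides (two
    curvature sign changes along the meridian); the "intermediate" bulge
    merges into the apex itself, so only its basal shoulder flips the
    meridian curvature (one sign change).
    """
    # the intermediate bump is centered beyond the pole: only its rising
    # shoulder lives on the wall, so the meridian flips curvature once
    u0 = 1.08 if params.aneurysm == "intermediate" else _BULGE_U0
    du = (u - u0) / params.bulge_sharpness
    dphi = np.arctan2(np.sin(phi - _BULGE_PHI0), np.cos(phi - _BULGE_PHI0))
    return np.exp(-0.5 * du**2 - 0.5 * (dphi / _BULGE_PHI_WIDTH) ** 2)


def _endocardial_shell(params: LVGenParams):
    """Vertex grid (rings x azimuth), apex vertex, lid vertices and faces."""
    nu, nphi = params.n_rings, params.n_azimuth
    L = params.long_axis
    # truncated prolate spheroid: polar angle from base rim to apex
    psi0 = np.radians(55.0)
    a = L / (1.0 + np.cos(psi0))
    b = params.sphericity * L / 2.0
    z_base = a * np.cos(psi0)

    u = (np.arange(nu) + 1) / (nu + 1)        # (0,1): rings between rim and apex
    u_full = np.concatenate([[0.0], u])       # rim at u=0
    psi = psi0 + u_full * (np.pi - psi0)
    phi = 2 * np.pi * np.arange(nphi) / nphi

    P, U = np.meshgrid(phi, u_full, indexing="ij")
    PSI = psi0 + U * (np.pi - psi0)
    rho = b * np.sin(PSI)
    z = a * np.cos(PSI)
    verts = np.stack([rho * np.cos(P), rho * np.sin(P), z], axis=-1)
    verts = verts.transpose(1, 0, 2).reshape(-1, 3)   # ring-major ordering

    n_shell = (nu + 1) * nphi
    apex = np.array([0.0, 0.0, -a])
    lid_center = np.array([0.0, 0.0, z_base])
    vertices = np.vstack([verts, apex[None], lid_center[None]])
    i_apex, i_lid = n_shell, n_shell + 1

    faces = []
    for k in range(nu):
        for l in range(nphi):
            a0 = k * nphi + l
            a1 = k * nphi + (l + 1) % nphi
            b0 = (k + 1) * nphi + l
            b1 = (k + 1) * nphi + (l + 1) % nphi
            faces.append([a0, b0, b1])
            faces.append([a0, b1, a1])
    last = nu * nphi
    for l in range(nphi):  # apex fan
        faces.append([last + l, i_apex, last + (l + 1) % nphi])
    for l in range(nphi):  # basal lid fan (flat, outward = +z)
        faces.append([l, (l + 1) % nphi, i_lid])
    faces = np.asarray(faces, np.int64)
    frame = dict(a=a, b=b, z_base=z_base, psi0=psi0, i_apex=i_apex, i_lid=i_lid,
                 nu=nu, nphi=nphi, n_shell=n_shell)
    return vertices, faces, frame


def _landmarks(frame, params: LVGenParams) -> dict:
    """Annulus rings on the base plane: a cardioid mitral ring (lobe away
    from the outflow tract) and an elliptical aortic ring, scaled to the
    basal radius; RCA ostium just outside the anterior rim."""
    b, z_base = frame["b"], frame["z_base"]
    th = 2 * np.pi * np.arange(18) / 18
    a_card = 0.28 * b
    r_card = a_card * (1 + np.cos(th - np.pi))  # lobe toward -x
    mitral_pole = np.array([0.12 * b, 0.0, z_base])
    mitral = mitral_pole + np.stack(
        [r_card * np.cos(th), r_card * np.sin(th), np.zeros_like(th)], -1)
    aortic_c = np.array([0.50 * b, 0.12 * b, z_base])
    ax1, ax2 = 0.34 * b, 0.28 * b
    aortic = aortic_c + np.stack(
        [ax1 * np.cos(th), ax2 * np.sin(th), np.zeros_like(th)], -1)
    rca = np.array([1.05 * b, 0.0, z_base + 2.0])
    return {
        "apex": np.array([0.0, 0.0, -frame["a"]]),
        "rca_ostium": rca,
        "mitral_annulus": mitral,
        "aortic_annulus": aortic,
    }


def _vertex_uv(frame):
    """(u, phi) parameter per vertex; apex u=1, lid vertices u=0."""
    nu, nphi, n_shell = frame["nu"], frame["nphi"], frame["n_shell"]
    u_full = np.concatenate([[0.0], (np.arange(nu) + 1) / (nu + 1)])
    u = np.repeat(u_full, nphi)
    phi = np.tile(2 * np.pi * np.arange(nphi) / nphi, nu + 1)
    u = np.concatenate([u, [1.0, 0.0]])
    phi = np.concatenate([phi, [0.0, 0.0]])
    return u, phi


def _apply_bulge(vertices: np.ndarray, u: np.ndarray, phi: np.ndarray,
                 params: LVGenParams) -> np.ndarray:
    """Displace the shell outward over the bulge region.

    "true": cylindrical-radial offset tapered to zero at rim and apex — a
    necked sac beside the apex. "intermediate": sphere-radial expansion
    tapered only at the base, so the bulge merges into the apex cap.
    """
    if params.bulge_amplitude <= 0:
        return vertices
    g = _bulge_profile(u, phi, params) * params.bulge_amplitude
    out = vertices.copy()
    if params.aneurysm == "intermediate":
        taper = np.clip(u / 0.3, 0.0, 1.0) ** 2
        norms = np.linalg.norm(vertices, axis=1)
        dirs = vertices / np.maximum(norms, 1e-12)[:, None]
        out += (g * taper)[:, None] * dirs
    else:
        taper = np.sin(np.pi * np.clip(u, 0.0, 1.0)) ** 2
        rho = np.hypot(vertices[:, 0], vertices[:, 1])
        dirs = np.zeros_like(vertices)
        ok = rho > 1e-9
        dirs[ok, 0] = vertices[ok, 0] / rho[ok]
        dirs[ok, 1] = vertices[ok, 1] / rho[ok]
        out += (g * taper)[:, None] * dirs
    return out


def make_lv(params: LVGenParams) -> LVGeometry:
    """Generate one synthetic LV case with landmarks, contraction and thickness.

    The displacement field points along the inward normal, tapers to zero at
    the fixed basal lid, is modulated per AHA segment by the hypokinesis
    map, and is globally scaled so the achieved EF matches ``target_ef``
    within 0.5%. Aneurysmatic variants add a thin-walled apical-anterior
    bulge whose axial sharpness separates "true" (two curvature sign
    changes) from "intermediate" (one) morphology.
    """
    vertices, faces, frame = _endocardial_shell(params)
    landmarks = _landmarks(frame, params)
    u, phi = _vertex_uv(frame)
    vertices = _apply_bulge(vertices, u, phi, params)
    ed = SurfaceMesh(vertices, faces, landmarks)

    bump = _bulge_profile(u, phi, params)

    # wall thickness: base value, mildly thicker mid-wall, thinned over the bulge
    rng = np.random.default_rng(params.seed)
    thickness = params.wall_thickness * (1.0 + 0.05 * np.sin(np.pi * u))
    if params.thinning > 0 and params.aneurysm != "none":
        # saturating profile: the whole bulge core loses the full thinning
        # fraction, not just its very peak
        thin_profile = np.clip(bump / 0.6, 0.0, 1.0)
        thickness = thickness * (1.0 - params.thinning * thin_profile)

    # raw inward motion: vertex normals, tapered to zero at the basal rim/lid
    tm = ed.as_trimesh()
    normals = np.asarray(tm.vertex_normals, float)  # outward for this orientation
    taper = np.sin(np.clip(u, 0.0, 1.0) * np.pi / 2) ** 0.5
    taper[frame["i_lid"]] = 0.0
    lid_ring = np.arange(frame["nphi"])  # rim ring is welded to the lid
    taper[lid_ring] = 0.0
    motion = -normals * taper[:, None]

    segmap = assign_segments(ed)
    seg_mult = np.ones(ed.n_vertices)
    for seg, mult in params.hypokinesis.items():
        seg_mult[segmap.labels == int(seg)] = float(mult)
    if params.aneurysm in ("true", "intermediate", "hypokinetic") and not params.hypokinesis:
        # aneurysmatic wall moves little where it is thin
        seg_mult = seg_mult * (1.0 - 0.85 * bump)
    motion = motion * seg_mult[:, None]

    # scale so that volume(ED + scale*motion) = (1 - EF) * EDV
    coeffs = volume_polynomial(ed, motion * 10.0)  # probe with a 10 mm stroke
    poly = np.polynomial.Polynomial(coeffs)
    edv = poly(0.0)
    target = (1.0 - params.target_ef) * edv

    def resid(s):
        return poly(s) - target

    if resid(1.0) > 0:
        raise ValueError(
            f"target EF {params.target_ef} unreachable: motion field achieves at most "
            f"EF {(edv - poly(1.0)) / edv:.3f} with the given hypokinesis map")
    scale = brentq(resid, 0.0, 1.0, xtol=1e-10)
    displacement = motion * 10.0 * scale

    es = SurfaceMesh(vertices + displacement, faces)
    md = CaseMetadata(mr_grade=params.mr_grade,
                      aneurysm_class=params.aneurysm)
    return LVGeometry(ed_mesh=ed, es_mesh=es, displacement=displacement,
                      thickness=thickness, metadata=md)


@dataclass
class CohortSpec:
    """A generated cohort plus its ground-truth generating directions."""

    cases: list
    mode_directions: np.ndarray  # (7m+3, k), orthonormal
    amplitudes: np.ndarray       # (n, k) sampled mode weights
    noise_sigma: float
    seed: int


def _smooth_feature_modes(base: LVGeometry, u, phi, k: int, rng) -> np.ndarray:
    """k smooth, mutually orthonormal feature-space directions.

    Low-order harmonics in the surface parameters drive the coordinate,
    displacement and thickness channels so planted modes look like anatomy,
    not noise.
    """
    m = base.ed_mesh.n_vertices
    normals = np.asarray(base.ed_mesh.as_trimesh().vertex_normals, float)
    cols = []
    harmonics = [(1, 0), (0, 1), (1, 1), (2, 0), (2, 1), (0, 2), (1, 2), (3, 0)]
    for mode_i in range(k):
        p, q = harmonics[mode_i % len(harmonics)]
        pattern = np.cos(p * np.pi * u) * np.cos(q * phi + 0.3 * mode_i)
        vec = np.zeros(7 * m + 3)
        which = mode_i % 3
        if which == 0:    # radial shape change
            vec[: 3 * m] = (normals * pattern[:, None]).ravel()
        elif which == 1:  # contraction-pattern change
            vec[3 * m : 6 * m] = (normals * pattern[:, None]).ravel()
        else:             # wall-thickness change
            vec[6 * m : 7 * m] = pattern
        cols.append(vec)
    Q, _ = np.linalg.qr(np.column_stack(cols))
    return Q


def make_cohort(n: int, mode_sigmas=(4.0, 2.0), noise: float = 0.0,
                seed: int = 0, params: Optional[LVGenParams] = None) -> CohortSpec:
    """Cohort of corresponded cases: base LV + planted orthonormal modes + noise.

    Mode weights are zero-mean Gaussian with the given per-mode standard
    deviations (mm); ``noise`` adds i.i.d. Gaussian perturbation to every
    feature. Same seed ⇒ identical cohort.
    """
    from .ssm import ShapeVector, assemble_feature_vector, shape_vector_to_geometry

    if n < 2:
        raise ValueError("cohort needs n >= 2")
    params = params or LVGenParams()
    rng = np.random.default_rng(seed)
    base = make_lv(params)
    u, phi = _vertex_uv(dict(nu=params.n_rings, nphi=params.n_azimuth,
                             n_shell=(params.n_rings + 1) * params.n_azimuth))
    k = len(mode_sigmas)
    Q = _smooth_feature_modes(base, u, phi, k, rng)
    base_vec = assemble_feature_vector(base).pack()
    amps = rng.normal(0.0, 1.0, size=(n, k)) * np.asarray(mode_sigmas)
    cases = []
    lm = base.ed_mesh.landmarks
    for i in range(n):
        vec = base_vec + Q @ amps[i]
        if noise > 0:
            vec = vec + rng.normal(0.0, noise, size=vec.shape)
        geo = shape_vector_to_geometry(ShapeVector.unpack(vec), base.ed_mesh.faces,
                                       landmarks=lm, metadata=base.metadata)
        cases.append(geo)
    return CohortSpec(cases, Q, amps, noise, seed)


# ---------------------------------------------------------------------------
# Analytic flow fields


def make_flow_snapshot(kind: str, dims=(16, 16, 16), spacing=(0.005, 0.005, 0.005),
                       origin=(0.0, 0.0, 0.0), **params) -> FieldSnapshot:
    """Analytic velocity field sampled at cell centers.

    Kinds: ``uniform`` (speed, direction), ``rigid_rotation`` (omega, axis
    through the grid center), ``simple_shear`` (shear_rate, u_x = γ̇·y),
    ``poiseuille`` (u_max, channel across y), ``vortex`` (Taylor–Green-like
    cellular flow, amplitude).
    """
    grid = VoxelGrid(tuple(dims), tuple(spacing), tuple(origin))
    X = grid.cell_centers()
    center = np.asarray(origin) + np.asarray(dims) * np.asarray(spacing) / 2.0
    R = X - center
    v = np.zeros(X.shape)
    if kind == "uniform":
        speed = params.get("speed", 1.0)
        direction = np.asarray(params.get("direction", (1.0, 0.0, 0.0)), float)
        direction = direction / np.linalg.norm(direction)
        v[:] = speed * direction
    elif kind == "rigid_rotation":
        omega = params.get("omega", 10.0)
        axis = np.asarray(params.get("axis", (0.0, 0.0, 1.0)), float)
        axis = axis / np.linalg.norm(axis)
        v = np.cross(omega * axis, R)
    elif kind == "simple_shear":
        rate = params.get("shear_rate", 100.0)
        v[..., 0] = rate * R[..., 1]
    elif kind == "poiseuille":
        umax = params.get("u_max", 1.0)
        half = dims[1] * spacing[1] / 2.0
        v[..., 0] = umax * (1.0 - (R[..., 1] / half) ** 2)
    elif kind == "vortex":
        amp = params.get("amplitude", 1.0)
        Lx = dims[0] * spacing[0]
        Ly = dims[1] * spacing[1]
        x, y = X[..., 0] - origin[0], X[..., 1] - origin[1]
        v[..., 0] = amp * np.sin(np.pi * x / Lx) * np.cos(np.pi * y / Ly)
        v[..., 1] = -amp * np.cos(np.pi * x / Lx) * np.sin(np.pi * y / Ly)
    else:
        raise ValueError(f"unknown field kind '{kind}'")
    pressure = params.get("pressure")
    scalars = params.get("scalars", {})
    return FieldSnapshot(params.get("time", 0.0), grid, v, pressure, scalars)


def stirred_box_velocity(grid: VoxelGrid, through_flow: float,
                         stir_amplitude: float) -> dict:
    """Staggered, discretely divergence-free box flow with through-flow.

    Uniform through-flow ``through_flow`` (m/s) along +x carries fluid from
    the x− (inflow) to the x+ (outflow) face; a cellular stirring vortex of
    amplitude ``stir_amplitude`` (from a stream function sampled at cell
    corners, so the discrete divergence vanishes exactly) mixes the box
    without any net wall flux. Returned as staggered face arrays for
    :func:`advect_scalar`.
    """
    nx, ny, nz = grid.dims
    dx, dy, dz = grid.spacing
    Lx, Ly = nx * dx, ny * dy
    # stream function at cell corners (x-y plane), constant in z
    xc = np.arange(nx + 1) * dx
    yc = np.arange(ny + 1) * dy
    PSI = stir_amplitude * (Lx / np.pi) * np.outer(
        np.sin(np.pi * xc / Lx), np.sin(np.pi * yc / Ly))
    # u on x-faces: u = dψ/dy -> difference along y of corner values
    u_face = (PSI[:, 1:] - PSI[:, :-1]) / dy          # (nx+1, ny)
    u = through_flow + np.repeat(u_face[:, :, None], nz, axis=2)
    # v on y-faces: v = -dψ/dx
    v_face = -(PSI[1:, :] - PSI[:-1, :]) / dx         # (nx, ny+1)
    v = np.repeat(v_face[:, :, None], nz, axis=2)
    w = np.zeros((nx, ny, nz + 1))
    return {"x": u, "y": v, "z": w}


def make_wellmixed_series(ef: float, cycles: int = 8, samples_per_cycle: int = 20,
                          period: float = 0.8):
    """Closed-form perfectly-mixed washout series.

    After k cycles the old-blood fraction is (1−EF)^k and the fresh fraction
    1−(1−EF)^k; within a cycle the series interpolates linearly. Returns
    ``(times, fresh, old)``.
    """
    if not (0.0 < ef < 1.0):
        raise ValueError("EF must be in (0, 1)")
    k_nodes = np.arange(cycles + 1)
    old_nodes = (1.0 - ef) ** k_nodes
    times = np.linspace(0.0, cycles * period, cycles * samples_per_cycle + 1)
    old = np.interp(times / period, k_nodes, old_nodes)
    return times, 1.0 - old, old
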