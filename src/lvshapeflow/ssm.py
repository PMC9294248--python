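"""Multi-channel statistical shape model of the left ventricle.

Each training case contributes one feature column stacking, in order, the
3m end-diastolic vertex coordinates s, the 3m displacement components d
(ED→ES contraction), the m wall-thickness scalars v, and the 3 RCA-ostium
landmark coordinates p — a vector of length 7m+3, all in mm. PCA of the
column-centered matrix (1/(n−1) covariance normalization, via thin SVD)
gives the mean shape S̄, the orthonormal mode matrix X and per-mode
variances; new anatomies are synthesized as S = S̄ + X·b.

Channels are deliberately not rescaled before PCA (all live in mm); an
optional per-channel weighting is available for sensitivity studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .geometry import CaseMetadata, LVGeometry, SurfaceMesh

__all__ = [
    "ShapeVector",
    "FeatureMatrix",
    "SSModel",
    "assemble_feature_vector",
    "fit_model",
    "synthesize",
    "cumulative_variance",
    "modes_for_variance",
    "group_cases",
    "cohort_mean",
    "shape_vector_to_geometry",
    "save_model",
    "load_model",
]


@dataclass
class ShapeVector:
    """One case in feature space: coordinates, contraction, thickness, RCA."""

    s: np.ndarray  # (m, 3) ED vertex coordinates, mm
    d: np.ndarray  # (m, 3) displacement vectors, mm
    v: np.ndarray  # (m,)  wall thickness, mm
    p: np.ndarray  # (3,)  RCA ostium, mm

    def __post_init__(self):
        self.s = np.asarray(self.s, float).reshape(-1, 3)
        self.d = np.asarray(self.d, float).reshape(-1, 3)
        self.v = np.asarray(self.v, float).ravel()
        self.p = np.asarray(self.p, float).reshape(3)
        m = len(self.s)
        if len(self.d) != m or len(self.v) != m:
            raise ValueError("channel lengths disagree")

    @property
    def m(self) -> int:
        return len(self.s)

    def pack(self) -> np.ndarray:
        """Flatten to the canonical 7m+3 layout: all s, all d, all v, then p."""
        return np.concatenate([self.s.ravel(), self.d.ravel(), self.v, self.p])

    @staticmethod
    def unpack(vec: np.ndarray) -> "ShapeVector":
        vec = np.asarray(vec, float).ravel()
        if (len(vec) - 3) % 7:
            raise ValueError(f"length {len(vec)} is not 7m+3")
        m = (len(vec) - 3) // 7
        return ShapeVector(
            vec[: 3 * m].reshape(m, 3),
            vec[3 * m : 6 * m].reshape(m, 3),
            vec[6 * m : 7 * m],
            vec[7 * m :],
        )


def assemble_feature_vector(case: LVGeometry) -> ShapeVector:
    """Stack a corresponded case into its feature-space column."""
    if case.displacement is None or case.thickness is None:
        raise ValueError("case needs displacement and thickness fields")
    rca = case.ed_mesh.landmark_point("rca_ostium")
    return ShapeVector(case.ed_mesh.vertices, case.displacement, case.thickness, rca)


def shape_vector_to_geometry(sv: ShapeVector, faces: np.ndarray,
                             landmarks: Optional[dict] = None,
                             metadata: Optional[CaseMetadata] = None) -> LVGeometry:
    """Unpack a feature vector into an LV case on the given template faces."""
    lm = dict(landmarks or {})
    lm["rca_ostium"] = sv.p.copy()
    ed = SurfaceMesh(sv.s.copy(), np.asarray(faces, np.int64), lm)
    es = SurfaceMesh(sv.s + sv.d, np.asarray(faces, np.int64))
    return LVGeometry(ed_mesh=ed, es_mesh=es, displacement=sv.d.copy(),
                      thickness=np.clip(sv.v, 0.0, None), metadata=metadata)


@dataclass
class FeatureMatrix:
    """Training matrix: 7m+3 feature rows by n case columns."""

    M: np.ndarray
    case_ids: Sequence[str]

    def __post_init__(self):
        self.M = np.asarray(self.M, float)
        if self.M.ndim != 2:
            raise ValueError("M must be 2-D (features x cases)")
        if (self.M.shape[0] - 3) % 7:
            raise ValueError("row count is not 7m+3")
        if len(self.case_ids) != self.M.shape[1]:
            raise ValueError("case_ids length != column count")

    @property
    def n(self) -> int:
        return self.M.shape[1]

    @property
    def m(self) -> int:
        return (self.M.shape[0] - 3) // 7

    @staticmethod
    def from_cases(cases: Sequence[LVGeometry], case_ids: Optional[Sequence[str]] = None):
        cols = [assemble_feature_vector(c).pack() for c in cases]
        ids = list(case_ids) if case_ids is not None else [f"case{i:03d}" for i in range(len(cols))]
        return FeatureMatrix(np.column_stack(cols), ids)


@dataclass
class SSModel:
    """PCA shape model: mean S̄, orthonormal modes X, per-mode variances."""

    mean: np.ndarray         # (7m+3,)
    modes: np.ndarray        # (7m+3, k), orthonormal columns
    eigenvalues: np.ndarray  # (k,), descending, mm² scale
    n_train: int

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def m(self) -> int:
        return (len(self.mean) - 3) // 7

    def mode_std(self) -> np.ndarray:
        return np.sqrt(np.clip(self.eigenvalues, 0.0, None))

    def project(self, vec: np.ndarray) -> np.ndarray:
        """Mode weights b = Xᵀ·(vec − mean)."""
        return self.modes.T @ (np.asarray(vec, float).ravel() - self.mean)


def fit_model(matrix: FeatureMatrix, channel_weights=None) -> SSModel:
    """Fit the PCA model by thin SVD of the column-centered matrix.

    Eigenvalues are singular values squared over (n−1). Mode signs are fixed
    so each mode's largest-magnitude loading is positive, which makes the
    model deterministic across platforms. ``channel_weights`` optionally
    scales the (s, d, v, p) channels before the fit (defaults to 1).
    """
    M = matrix.M
    if matrix.n < 2:
        raise ValueError("model fitting needs at least 2 training cases")
    if channel_weights is not None:
        ws, wd, wv, wp = channel_weights
        m = matrix.m
        w = np.concatenate([np.full(3 * m, ws), np.full(3 * m, wd),
                            np.full(m, wv), np.full(3, wp)])
        M = M * w[:, None]
    mean = M.mean(axis=1)
    centered = M - mean[:, None]
    U, s, _ = np.linalg.svd(centered, full_matrices=False)
    eigvals = s**2 / (matrix.n - 1)
    # deterministic sign: largest-|loading| entry of every mode positive
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return SSModel(mean=mean, modes=U * signs, eigenvalues=eigvals, n_train=matrix.n)


def synthesize(model: SSModel, b: np.ndarray, clamp: bool = False,
               n_std: float = 3.0) -> np.ndarray:
    """Synthesize a shape vector S = S̄ + X·b.

    With ``clamp=True`` each weight is limited to ±n_std standard deviations
    of its mode, guarding exported meshes against self-intersecting extremes.
    """
    b = np.asarray(b, float).ravel()
    if len(b) > model.n_modes:
        raise ValueError(f"{len(b)} weights for {model.n_modes} modes")
    if clamp:
        lim = n_std * model.mode_std()[: len(b)]
        b = np.clip(b, -lim, lim)
    return model.mean + model.modes[:, : len(b)] @ b


def cumulative_variance(model: SSModel) -> np.ndarray:
    """Cumulative fraction of total variance captured by the first k modes."""
    total = model.eigenvalues.sum()
    if total <= 0:
        raise ValueError("model has zero total variance")
    return np.cumsum(model.eigenvalues) / total


def modes_for_variance(model: SSModel, target: float) -> int:
    """Smallest mode count whose cumulative variance reaches ``target``."""
    if not (0.0 < target <= 1.0):
        raise ValueError("target must be in (0, 1]")
    cum = cumulative_variance(model)
    if target == 1.0:
        return int(np.sum(model.eigenvalues > 1e-12 * model.eigenvalues[0]))
    return int(np.searchsorted(cum, target - 1e-12) + 1)


# ---------------------------------------------------------------------------
# Subcohort grouping and mean cases

PRIMARY_GROUPS = ("A0ML", "A0MH", "A1ML", "A1MH")
MORPHOLOGY_GROUPS = {"true": "A1T", "intermediate": "A1I", "hypokinetic": "A1HK"}
MR_HIGH_THRESHOLD = 2.0  # grade >= II counts as high MR


def group_cases(metadata: Sequence[CaseMetadata]):
    """Assign each case its subcohort labels.

    Primary split: A0/A1 by aneurysm absence/presence crossed with ML/MH by
    MR grade below / at-or-above grade II. Aneurysmatic cases additionally
    get a morphology label (A1T/A1I/A1HK); cases whose aneurysm shape was
    not classified are excluded from that secondary grouping.

    Returns a list of label tuples, one per case.
    """
    out = []
    for i, md in enumerate(metadata):
        if md is None:
            raise ValueError(f"case {i}: missing metadata")
        labels = []
        has_aneurysm = md.aneurysm_class != "none"
        mr = "MH" if md.mr_grade >= MR_HIGH_THRESHOLD else "ML"
        labels.append(("A1" if has_aneurysm else "A0") + mr)
        if has_aneurysm and md.aneurysm_class in MORPHOLOGY_GROUPS:
            labels.append(MORPHOLOGY_GROUPS[md.aneurysm_class])
        out.append(tuple(labels))
    return out


def cohort_mean(vectors: Sequence[ShapeVector]) -> ShapeVector:
    """Component-wise mean case of a subcohort (equals a subcohort PCA mean)."""
    if len(vectors) == 0:
        raise ValueError("empty subcohort")
    stacked = np.column_stack([v.pack() for v in vectors])
    return ShapeVector.unpack(stacked.mean(axis=1))


# ---------------------------------------------------------------------------
# Serialization: directory with npy payloads and a JSON manifest


def save_model(model: SSModel, path, faces: Optional[np.ndarray] = None) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "mean.npy", model.mean)
    np.save(path / "modes.npy", model.modes)
    np.save(path / "eigenvalues.npy", model.eigenvalues)
    if faces is not None:
        np.save(path / "faces.npy", np.asarray(faces, np.int64))
    manifest = {
        "m": model.m,
        "n_train": model.n_train,
        "n_modes": model.n_modes,
        "channel_layout": ["s:3m", "d:3m", "v:m", "p:3"],
        "units": "mm",
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_model(path):
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    model = SSModel(
        mean=np.load(path / "mean.npy"),
        modes=np.load(path / "modes.npy"),
        eigenvalues=np.load(path / "eigenvalues.npy"),
        n_train=manifest["n_train"],
    )
    faces = None
    if (path / "faces.npy").exists():
        faces = np.load(path / "faces.npy")
    return model, faces
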