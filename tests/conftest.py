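"""Shared fixtures: synthetic LV cases and simple analytic meshes."""

import numpy as np
import pytest
import trimesh

from lvshapeflow.geometry import SurfaceMesh
from lvshapeflow.synthetic import LVGenParams, make_lv


@pytest.fixture(scope="session")
def default_lv():
    return make_lv(LVGenParams(seed=0))


@pytest.fixture(scope="session")
def aneurysm_lv():
    return make_lv(LVGenParams(aneurysm="true", seed=1))


@pytest.fixture(scope="session")
def icosphere30():
    s = trimesh.creation.icosphere(3, 30.0)
    return SurfaceMesh(s.vertices, s.faces)


def sphere_with_landmarks(radius: float, subdivisions: int = 3) -> SurfaceMesh:
    """Sphere carrying LV-style landmarks: apex at the bottom pole, annulus
    rings and RCA near the top."""
    s = trimesh.creation.icosphere(subdivisions, radius)
    th = 2 * np.pi * np.arange(18) / 18
    r = radius
    lm = {
        "apex": np.array([0.0, 0.0, -r]),
        "rca_ostium": np.array([1.05 * r, 0.0, 0.55 * r]),
        "mitral_annulus": np.column_stack([
            0.4 * r * np.cos(th) - 0.2 * r, 0.4 * r * np.sin(th),
            np.full(18, 0.6 * r)]),
        "aortic_annulus": np.column_stack([
            0.2 * r * np.cos(th) + 0.3 * r, 0.2 * r * np.sin(th),
            np.full(18, 0.6 * r)]),
    }
    return SurfaceMesh(s.vertices, s.faces, lm)


@pytest.fixture(scope="session")
def sphere_case_30():
    return sphere_with_landmarks(30.0)


@pytest.fixture(scope="session")
def sphere_case_33():
    return sphere_with_landmarks(33.0)


@pytest.fixture(scope="session")
def cube_mesh():
    b = trimesh.creation.box(extents=(10.0, 10.0, 10.0))
    return SurfaceMesh(b.vertices, b.faces)
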