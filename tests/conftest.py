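"""Shared fixtures: analytic meshes and small phantom hemispheres."""

import numpy as np
import pytest
import trimesh

from myelosurf.geometry import SurfacePair, TriangleMesh


def make_icosphere(subdivisions: int = 3, radius: float = 1.0) -> TriangleMesh:
    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(s.vertices), np.asarray(s.faces))


def make_planar_grid(n: int = 31, spacing: float = 1.0) -> TriangleMesh:
    """Right-triangulated square grid in the z = 0 plane."""
    xx, yy = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing, indexing="ij")
    vertices = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a, b, c, d = i * n + j, (i + 1) * n + j, i * n + j + 1, (i + 1) * n + j + 1
            faces.append([a, b, c])
            faces.append([b, d, c])
    return TriangleMesh(vertices, np.array(faces))


def interior_vertices(n: int, margin: int = 2) -> np.ndarray:
    """Indices of grid vertices at least `margin` rows from the border."""
    idx = np.arange(n * n).reshape(n, n)
    return idx[margin:-margin, margin:-margin].ravel()


@pytest.fixture(scope="session")
def icosphere4():
    return make_icosphere(subdivisions=4, radius=10.0)


@pytest.fixture(scope="session")
def planar31():
    return make_planar_grid(31)


@pytest.fixture(scope="session")
def sphere_pair():
    """Concentric spheres, radii 9 and 10 mm."""
    s = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    v = np.asarray(s.vertices)
    f = np.asarray(s.faces)
    return SurfacePair(TriangleMesh(v * 9.0, f), TriangleMesh(v * 10.0, f))


@pytest.fixture(scope="session")
def random_pair():
    """A closed, randomly deformed white/pial pair."""
    s = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    v = np.asarray(s.vertices)
    f = np.asarray(s.faces)
    r1 = 9.0 + 0.5 * np.sin(3 * v[:, 0]) * np.cos(2 * v[:, 1])
    r2 = r1 + 1.0 + 0.3 * np.cos(4 * v[:, 2])
    return SurfacePair(TriangleMesh(v * r1[:, None], f), TriangleMesh(v * r2[:, None], f))


@pytest.fixture(scope="session")
def night_spec():
    from myelosurf.phantom import SpeciesSpec

    return SpeciesSpec(
        name="night_monkey",
        n_subjects=1,
        subdivisions=4,
        target_fractions={"MT+": 0.024, "AC": 0.025, "BA7": 0.023, "V1": 0.188},
        myelin_levels={"MT+": 0.8, "AC": 0.65, "BA7": -0.6, "V1": 0.7},
        mean_thickness_mm=2.0,
        total_area_scale=1.27,
        sampling_fwhm_mm=1.8,
        seed=11,
    )


@pytest.fixture(scope="session")
def night_hemisphere(night_spec):
    from myelosurf.phantom import make_hemisphere

    return make_hemisphere(night_spec, 0, "L")
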