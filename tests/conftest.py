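import numpy as np
import pytest
import trimesh

from adcascade import (
    CohortSpec,
    SurfaceMesh,
    combine_structures,
    generate_cohort,
    isomap,
    pairwise_distances,
)


@pytest.fixture
def tetra() -> SurfaceMesh:
    """Smallest closed triangulation: a tetrahedron."""
    verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return SurfaceMesh(verts, faces)


@pytest.fixture
def regular_tetra() -> SurfaceMesh:
    """Regular tetrahedron with unit edge length."""
    verts = np.array([[1.0, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / (2 * np.sqrt(2))
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return SurfaceMesh(verts, faces)


@pytest.fixture
def unit_cube() -> SurfaceMesh:
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces))


@pytest.fixture
def icosphere():
    def make(subdivisions: int = 3, radius: float = 1.0) -> SurfaceMesh:
        s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
        return SurfaceMesh(np.asarray(s.vertices), np.asarray(s.faces))

    return make


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (all four structures), shared across tests."""
    return generate_cohort(CohortSpec(seed=0))


@pytest.fixture(scope="session")
def hippo_embedding(default_cohort):
    """Bilateral hippocampal distance matrix and its 20-component embedding."""
    ids = [r.id for r in default_cohort]
    d_l = pairwise_distances([r.meshes["hippocampus_L"] for r in default_cohort], subject_ids=ids)
    d_r = pairwise_distances([r.meshes["hippocampus_R"] for r in default_cohort], subject_ids=ids)
    D = combine_structures(d_l, d_r)
    return D, isomap(D, k=10, m=20)
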