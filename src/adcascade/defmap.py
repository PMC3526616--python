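"""Vertex-wise signed surface-deformation maps between diagnostic groups.

For each atlas vertex, every subject's position is projected onto the
base mesh's outward unit normal; the map value is the difference of
group means of that normal component (positive = outward in the
first-named group relative to the second), with a per-vertex two-tailed
pooled-variance t-test p-value. Homogeneous atrophy shows as a
same-signed map; a volume-neutral local effect shows mixed signs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConnectivityMismatchError, DegenerateStatisticError
from .mesh_core import SurfaceMesh, vertex_normals, _format_ply
from .selection import two_sample_t


@dataclass
class DeformationMap:
    """Per-vertex signed displacement (mm) and p-value for one contrast."""

    displacement: np.ndarray
    p: np.ndarray
    contrast: tuple
    structure_tag: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vertex": np.arange(len(self.displacement)),
                "displacement_mm": self.displacement,
                "p": self.p,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_ply(self, base: SurfaceMesh, path) -> None:
        """Write the base mesh with displacement and p as vertex scalars,
        renderable in standard mesh viewers."""
        text = _format_ply(base, {"displacement": self.displacement, "p_value": self.p})
        with open(str(path), "w") as fh:
            fh.write(text)


def vertex_group_difference(
    meshes_a: list[SurfaceMesh],
    meshes_b: list[SurfaceMesh],
    base: SurfaceMesh,
    contrast: tuple = ("A", "B"),
) -> DeformationMap:
    """Signed normal-direction group-mean difference map (a minus b)."""
    if not meshes_a or not meshes_b:
        raise ValueError("both groups must be nonempty")
    for m in list(meshes_a) + list(meshes_b):
        if not base.same_connectivity(m):
            raise ConnectivityMismatchError("all meshes must share the base connectivity")
    normals = vertex_normals(base)

    def normal_components(meshes):
        # (n_subjects, V): outward-normal coordinate of each vertex
        pos = np.stack([m.vertices for m in meshes])
        return np.einsum("svk,vk->sv", pos - base.vertices, normals)

    comp_a = normal_components(meshes_a)
    comp_b = normal_components(meshes_b)
    disp = comp_a.mean(axis=0) - comp_b.mean(axis=0)
    pvals = np.ones(base.n_vertices)
    if len(meshes_a) >= 2 and len(meshes_b) >= 2:
        for v in range(base.n_vertices):
            try:
                _, pvals[v] = two_sample_t(comp_a[:, v], comp_b[:, v])
            except DegenerateStatisticError:
                # zero within-group variance: difference is exact
                pvals[v] = 0.0 if disp[v] != 0 else 1.0
    return DeformationMap(disp, pvals, tuple(contrast), base.structure_tag)
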