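"""Triangulated surface meshes: data model, OFF/PLY I/O, and geometric measures.

All subjects of one anatomical structure share a single atlas-induced
triangulation, so a mesh is a dense ``(V, 3)`` float array of vertex
positions in millimetres plus a shared ``(F, 3)`` integer triangle array
(0-based indices). Meshes are required to be closed orientable 2-manifolds
of genus zero, the topology guaranteed by atlas injection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import MeshParseError, MeshValidationError

STRUCTURE_TAGS = (
    "hippocampus_L",
    "hippocampus_R",
    "ventricle_L",
    "ventricle_R",
    "synthetic",
)

#: triangles with area below this (mm^2) are rejected as degenerate
_MIN_TRIANGLE_AREA = 1e-12


@dataclass
class SurfaceMesh:
    """A closed triangulated surface of one brain structure.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex positions in mm.
    triangles : (F, 3) int array
        Vertex index triples, 0-based, consistently wound.
    structure_tag : str
        One of :data:`STRUCTURE_TAGS`.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    structure_tag: str = "synthetic"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (V, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshValidationError("triangles must be an (F, 3) array")
        if self.structure_tag not in STRUCTURE_TAGS:
            raise MeshValidationError(
                f"unknown structure_tag {self.structure_tag!r}; "
                f"expected one of {STRUCTURE_TAGS}"
            )

    # -- basic counts -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_triangles(self) -> int:
        return int(self.triangles.shape[0])

    def edges(self) -> np.ndarray:
        """Distinct undirected edges as a sorted (E, 2) index array."""
        e = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def with_vertices(self, vertices: np.ndarray) -> "SurfaceMesh":
        """Copy of this mesh with new vertex positions, connectivity shared."""
        out = replace(self, vertices=np.asarray(vertices, dtype=np.float64))
        out.triangles = self.triangles  # share the atlas connectivity object
        return out

    def same_connectivity(self, other: "SurfaceMesh") -> bool:
        return (
            self.triangles is other.triangles
            or (self.triangles.shape == other.triangles.shape
                and bool(np.array_equal(self.triangles, other.triangles)))
        )


def validate_mesh(mesh: SurfaceMesh) -> None:
    """Check the closed-orientable-manifold invariants; raise on violation.

    Raises
    ------
    MeshValidationError
        On out-of-range indices, repeated-vertex triangles, near-zero-area
        triangles, edges not shared by exactly two triangles, or
        inconsistent winding across a shared edge.
    """
    v, t = mesh.vertices, mesh.triangles
    if len(t) == 0 or len(v) == 0:
        raise MeshValidationError("empty mesh")
    if t.min() < 0 or t.max() >= len(v):
        bad = int(np.argwhere((t < 0) | (t >= len(v)))[0, 0])
        raise MeshValidationError(
            f"triangle index out of range: triangle {bad} references index "
            f"{int(t.max())} but mesh has {len(v)} vertices"
        )
    if (
        (t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])
    ).any():
        raise MeshValidationError("degenerate triangle with a repeated vertex")
    areas = triangle_areas(mesh)
    if (areas < _MIN_TRIANGLE_AREA).any():
        i = int(np.argmin(areas))
        raise MeshValidationError(
            f"triangle {i} has near-zero area {areas[i]:.3e} mm^2"
        )
    # every undirected edge on exactly 2 triangles, and each directed edge
    # used exactly once (consistent orientation)
    directed = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    _, counts = np.unique(und, axis=0, return_counts=True)
    if not (counts == 2).all():
        n_bad = int((counts != 2).sum())
        raise MeshValidationError(
            f"non-manifold connectivity: {n_bad} edges not shared by exactly 2 triangles"
        )
    _, dcounts = np.unique(directed, axis=0, return_counts=True)
    if not (dcounts == 1).all():
        raise MeshValidationError("inconsistent triangle winding across a shared edge")


def euler_characteristic(mesh: SurfaceMesh) -> int:
    """V - E + F with E counted as distinct undirected edges."""
    return mesh.n_vertices - len(mesh.edges()) + mesh.n_triangles


def closed_triangulation_face_count(n_vertices: int) -> int:
    """Triangle count 2V - 4 of any closed genus-0 triangulation on V vertices.

    Follows from Euler's relation V - E + F = 2 with 3F = 2E.
    """
    if n_vertices < 4:
        raise ValueError(f"a closed triangulation needs >= 4 vertices, got {n_vertices}")
    return 2 * n_vertices - 4


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume (mm^3) by the divergence theorem; orientation-free.

    Sums signed tetrahedron volumes v0 . (v1 x v2) / 6 over triangles and
    returns the absolute value, so either consistent global orientation is
    accepted. Raises :class:`MeshValidationError` for open meshes.
    """
    validate_mesh(mesh)
    v = mesh.vertices[mesh.triangles]
    signed = np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6.0
    return float(abs(signed))


def triangle_areas(mesh: SurfaceMesh) -> np.ndarray:
    v = mesh.vertices[mesh.triangles]
    return 0.5 * np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)


def mesh_statistics(mesh: SurfaceMesh) -> dict:
    """Mean triangle area (mm^2) and mean distinct-edge length (mm)."""
    e = mesh.edges()
    lengths = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    return {
        "mean_triangle_area": float(triangle_areas(mesh).mean()),
        "mean_edge_length": float(lengths.mean()),
    }


def vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Unit outward vertex normals, area-weighted over incident triangles.

    Uses unnormalised cross products (twice the triangle area vector), so
    each incident triangle contributes proportionally to its area.
    """
    v = mesh.vertices[mesh.triangles]
    face_n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    n = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(n, mesh.triangles[:, k], face_n)
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    n = n / norms
    # flip to outward if the winding encloses negative signed volume
    signed = np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6.0
    if signed < 0:
        n = -n
    return n


# ---------------------------------------------------------------------------
# file I/O (ascii OFF and PLY)
# ---------------------------------------------------------------------------

_COORD_FMT = "%.17g"  # >= 9 significant digits, round-trips float64 exactly


def read_mesh(path, format: str | None = None, structure_tag: str = "synthetic") -> SurfaceMesh:
    """Read an ascii OFF or PLY mesh file.

    ``format`` is inferred from the extension when omitted. The returned
    mesh is validated against the closed-manifold invariants.
    """
    path = str(path)
    fmt = (format or path.rsplit(".", 1)[-1]).upper()
    with open(path) as fh:
        lines = fh.read().splitlines()
    if fmt == "OFF":
        mesh = _parse_off(lines, structure_tag)
    elif fmt == "PLY":
        mesh = _parse_ply(lines, structure_tag)
    else:
        raise ValueError(f"unsupported mesh format {fmt!r} (expected OFF or PLY)")
    validate_mesh(mesh)
    return mesh


def write_mesh(mesh: SurfaceMesh, path, format: str | None = None) -> None:
    """Write an ascii OFF or PLY file readable by :func:`read_mesh`."""
    if mesh.n_vertices == 0 or mesh.n_triangles == 0:
        raise MeshValidationError("refusing to write an empty mesh")
    path = str(path)
    fmt = (format or path.rsplit(".", 1)[-1]).upper()
    if fmt == "OFF":
        text = _format_off(mesh)
    elif fmt == "PLY":
        text = _format_ply(mesh)
    else:
        raise ValueError(f"unsupported mesh format {fmt!r} (expected OFF or PLY)")
    with open(path, "w") as fh:
        fh.write(text)


def _nonblank(lines):
    for i, raw in enumerate(lines):
        s = raw.split("#", 1)[0].strip()
        if s:
            yield i + 1, s  # 1-based line numbers for error messages


def _parse_off(lines, tag) -> SurfaceMesh:
    it = _nonblank(lines)
    try:
        lineno, header = next(it)
    except StopIteration:
        raise MeshParseError("line 1: empty OFF file") from None
    if header != "OFF":
        raise MeshParseError(f"line {lineno}: expected 'OFF' header, got {header!r}")
    try:
        lineno, counts = next(it)
        nv, nf, _ne = (int(x) for x in counts.split())
    except StopIteration:
        raise MeshParseError("unexpected end of file: missing OFF count line") from None
    except ValueError:
        raise MeshParseError(f"line {lineno}: malformed OFF count line {counts!r}") from None
    verts, faces = [], []
    for _ in range(nv):
        try:
            lineno, s = next(it)
            verts.append([float(x) for x in s.split()[:3]])
        except StopIteration:
            raise MeshParseError("unexpected end of file in vertex block") from None
        except (ValueError, IndexError):
            raise MeshParseError(f"line {lineno}: malformed vertex line {s!r}") from None
    for _ in range(nf):
        try:
            lineno, s = next(it)
            parts = [int(x) for x in s.split()]
        except StopIteration:
            raise MeshParseError("unexpected end of file in face block") from None
        except ValueError:
            raise MeshParseError(f"line {lineno}: malformed face line {s!r}") from None
        if not parts or parts[0] != 3 or len(parts) < 4:
            raise MeshParseError(f"line {lineno}: only triangular faces supported: {s!r}")
        faces.append(parts[1:4])
    return SurfaceMesh(np.array(verts), np.array(faces), tag)


def _format_off(mesh: SurfaceMesh) -> str:
    out = ["OFF", f"{mesh.n_vertices} {mesh.n_triangles} 0"]
    out += [" ".join(_COORD_FMT % c for c in v) for v in mesh.vertices]
    out += ["3 %d %d %d" % tuple(t) for t in mesh.triangles]
    return "\n".join(out) + "\n"


def _parse_ply(lines, tag) -> SurfaceMesh:
    if not lines or lines[0].strip() != "ply":
        raise MeshParseError("line 1: expected 'ply' magic")
    nv = nf = None
    vertex_props: list[str] = []
    in_vertex_element = False
    body_start = None
    for i, raw in enumerate(lines[1:], start=2):
        s = raw.strip()
        if s.startswith("comment") or not s:
            continue
        if s == "end_header":
            body_start = i
            break
        parts = s.split()
        if parts[0] == "format":
            if parts[1] != "ascii":
                raise MeshParseError(f"line {i}: only ascii PLY supported, got {parts[1]!r}")
        elif parts[0] == "element":
            in_vertex_element = parts[1] == "vertex"
            if parts[1] == "vertex":
                nv = int(parts[2])
            elif parts[1] == "face":
                nf = int(parts[2])
        elif parts[0] == "property" and in_vertex_element and parts[1] != "list":
            vertex_props.append(parts[-1])
    if body_start is None or nv is None or nf is None:
        raise MeshParseError("malformed PLY header: missing end_header or element counts")
    for axis in ("x", "y", "z"):
        if axis not in vertex_props:
            raise MeshParseError(f"PLY header missing vertex property {axis!r}")
    cols = [vertex_props.index(a) for a in ("x", "y", "z")]
    body = lines[body_start:]
    if len(body) < nv + nf:
        raise MeshParseError(
            f"unexpected end of file: expected {nv + nf} body lines, found {len(body)}"
        )
    verts, faces = [], []
    for j in range(nv):
        lineno = body_start + 1 + j
        parts = body[j].split()
        try:
            verts.append([float(parts[c]) for c in cols])
        except (ValueError, IndexError):
            raise MeshParseError(f"line {lineno}: malformed vertex line {body[j]!r}") from None
    for j in range(nf):
        lineno = body_start + 1 + nv + j
        parts = body[nv + j].split()
        try:
            ints = [int(x) for x in parts]
        except ValueError:
            raise MeshParseError(f"line {lineno}: malformed face line {body[nv + j]!r}") from None
        if not ints or ints[0] != 3 or len(ints) < 4:
            raise MeshParseError(f"line {lineno}: only triangular faces supported")
        faces.append(ints[1:4])
    return SurfaceMesh(np.array(verts), np.array(faces), tag)


def _format_ply(mesh: SurfaceMesh, vertex_scalars: dict[str, np.ndarray] | None = None) -> str:
    scalars = vertex_scalars or {}
    header = [
        "ply",
        "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property double x",
        "property double y",
        "property double z",
    ]
    header += [f"property double {name}" for name in scalars]
    header += [
        f"element face {mesh.n_triangles}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    extra = np.column_stack(list(scalars.values())) if scalars else None
    body = []
    for i, v in enumerate(mesh.vertices):
        row = [_COORD_FMT % c for c in v]
        if extra is not None:
            row += [_COORD_FMT % c for c in extra[i]]
        body.append(" ".join(row))
    body += ["3 %d %d %d" % tuple(t) for t in mesh.triangles]
    return "\n".join(header + body) + "\n"
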