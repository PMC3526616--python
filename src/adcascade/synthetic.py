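"""Synthetic case-control cohorts with planted CSF, volume and shape effects.

The generator emulates the statistical structure of a baseline
Alzheimer's-cascade cohort of four diagnostic groups — normal controls
(NC), stable and converting mild cognitive impairment (MCI-s / MCI-c),
and Alzheimer's disease (AD) — each subject carrying three CSF markers
(Abeta42, t-tau, p-tau, pg/mL) and corresponded surface meshes of the
bilateral hippocampus and lateral ventricles.

Planted structure, by design:

* CSF: all three markers separate NC from MCI and from AD, while only
  Abeta42 separates MCI from AD (tau means are identical for MCI and AD,
  i.e. tau has plateaued before conversion).
* Volume: a global shrinkage of the hippocampus (and expansion of the
  ventricles) shared by the MCI and AD groups, so volumes separate NC
  from the impaired groups but carry no MCI-vs-AD signal.
* Local shape: a volume-neutral paired outward/inward bump carried by AD
  and by MCI converters only, so MCI-vs-AD separation (and conversion
  signal) lives in localized shape, not in volume.
* Individual anatomy: smooth low-dimensional per-subject deformation
  modes plus size jitter plus small iid vertex jitter.

All randomness derives from a single cohort seed through per-subject
spawn keys, so adding a subject never perturbs any other subject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import mesh_core
from .errors import CohortError
from .mesh_core import SurfaceMesh, mesh_volume, vertex_normals, validate_mesh

GROUPS = ("NC", "MCI_s", "MCI_c", "AD")
STRUCTURES = ("hippocampus_L", "hippocampus_R", "ventricle_L", "ventricle_R")
CSF_MARKERS = ("abeta42", "t_tau", "p_tau")

#: semi-axes (mm) of the ellipsoidal stand-in for each atlas surface
DEFAULT_SEMI_AXES = {
    "hippocampus_L": (15.0, 8.0, 6.0),
    "hippocampus_R": (15.0, 8.0, 6.0),
    "ventricle_L": (25.0, 12.0, 9.0),
    "ventricle_R": (25.0, 12.0, 9.0),
}

# per-group CSF (mean, sd) in pg/mL; MCI-c draws from the AD distribution
# and MCI-s from the MCI distribution so conversion prediction has signal.
# Tau means are equal for MCI and AD (tau plateaus before conversion);
# only Abeta42 keeps separating MCI from AD.
DEFAULT_CSF_PARAMS = {
    "NC": {"abeta42": (205.0, 50.0), "t_tau": (70.0, 30.0), "p_tau": (25.0, 10.0)},
    "MCI_s": {"abeta42": (185.0, 45.0), "t_tau": (120.0, 50.0), "p_tau": (42.0, 16.0)},
    "MCI_c": {"abeta42": (135.0, 45.0), "t_tau": (120.0, 55.0), "p_tau": (42.0, 18.0)},
    "AD": {"abeta42": (135.0, 45.0), "t_tau": (120.0, 55.0), "p_tau": (42.0, 18.0)},
}

# linear global scale per group per structure: hippocampal shrinkage and
# ventricular expansion shared by all impaired groups (no MCI-vs-AD signal)
DEFAULT_VOLUME_EFFECT = {
    "NC": {"hippocampus_L": 1.0, "hippocampus_R": 1.0, "ventricle_L": 1.0, "ventricle_R": 1.0},
    "MCI_s": {"hippocampus_L": 0.95, "hippocampus_R": 0.95, "ventricle_L": 1.05, "ventricle_R": 1.05},
    "MCI_c": {"hippocampus_L": 0.95, "hippocampus_R": 0.95, "ventricle_L": 1.05, "ventricle_R": 1.05},
    "AD": {"hippocampus_L": 0.95, "hippocampus_R": 0.95, "ventricle_L": 1.05, "ventricle_R": 1.05},
}

# Table-1 age distributions per group (years)
DEFAULT_AGE_MEAN_SD = {
    "NC": (75.2, 5.2),
    "MCI_s": (74.0, 7.7),
    "MCI_c": (73.5, 6.9),
    "AD": (74.6, 9.3),
}

#: amplitude (mm) of the volume-neutral AD/MCI-c shape bump per structure
DEFAULT_BUMP_AMPLITUDE = {
    "hippocampus_L": 1.0,
    "hippocampus_R": 1.0,
    "ventricle_L": 1.2,
    "ventricle_R": 1.2,
}
#: unit direction whose nearest icosphere vertex hosts the default bump
#: (resolution independent; the antipode hosts the paired inward bump)
DEFAULT_BUMP_DIRECTION = (1.0, 1.0, 1.0)
DEFAULT_BUMP_WIDTH = 0.5  # angular width (radians)


@dataclass
class Bump:
    """A localized normal-direction Gaussian-profile deformation."""

    center_vertex: int
    amplitude: float  # mm, signed (negative = inward)
    width: float      # angular width (radians), Gaussian sigma

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise CohortError("bump width must be > 0")


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; defaults emulate the study sample."""

    group_sizes: dict = field(
        default_factory=lambda: {"NC": 72, "MCI_s": 86, "MCI_c": 25, "AD": 35}
    )
    csf_params: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_CSF_PARAMS)))
    volume_effect: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_VOLUME_EFFECT)))
    bump_effect: dict | None = None  # group -> structure -> list[Bump]; None = defaults
    vertex_noise_sd: float = 0.01  # mm, iid per-vertex jitter
    shape_mode_sd: float = 0.25    # mm RMS of smooth per-subject deformation modes
    shape_mode_width: float = 8.0  # mm, smoothing-kernel width defining the modes
    n_shape_modes: int = 8
    scale_jitter_sd: float = 0.06  # per-subject global size variability
    age_mean_sd: dict = field(default_factory=lambda: dict(DEFAULT_AGE_MEAN_SD))
    structures: tuple = STRUCTURES
    subdivision: int = 2
    semi_axes: dict = field(default_factory=lambda: dict(DEFAULT_SEMI_AXES))
    seed: int = 0

    def __post_init__(self) -> None:
        # normalize container types so specs compare equal across JSON trips
        self.structures = tuple(self.structures)
        self.semi_axes = {k: tuple(v) for k, v in self.semi_axes.items()}
        self.csf_params = {
            g: {m: tuple(v) for m, v in markers.items()}
            for g, markers in self.csf_params.items()
        }
        self.age_mean_sd = {g: tuple(v) for g, v in self.age_mean_sd.items()}
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise CohortError(f"unknown group {g!r}")
            if n < 0:
                raise CohortError(f"negative group size for {g}")
        for g, markers in self.csf_params.items():
            for m, (_, sd) in markers.items():
                if sd <= 0:
                    raise CohortError(f"non-positive CSF sd for {g}/{m}")
        if self.bump_effect is None:
            self.bump_effect = _default_bumps(self.structures, self.subdivision)

    @property
    def total(self) -> int:
        return sum(self.group_sizes.values())

    def to_json(self, path) -> None:
        d = asdict(self)  # recurses into Bump dataclasses
        d["structures"] = list(self.structures)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if d.get("bump_effect") is not None:
            d["bump_effect"] = {
                g: {s: [Bump(**b) for b in bumps] for s, bumps in by_s.items()}
                for g, by_s in d["bump_effect"].items()
            }
        return cls(**d)


def default_bump_center(subdivision: int) -> int:
    """Icosphere vertex closest to :data:`DEFAULT_BUMP_DIRECTION`."""
    ico = trimesh.creation.icosphere(subdivisions=subdivision, radius=1.0)
    u = np.asarray(DEFAULT_BUMP_DIRECTION, dtype=float)
    return int(np.argmax(np.asarray(ico.vertices) @ (u / np.linalg.norm(u))))


def antipodal_vertex(subdivision: int, center_vertex: int) -> int:
    """Index of the vertex diametrically opposite ``center_vertex`` on the
    subdivided icosphere (the icosphere is centrally symmetric)."""
    ico = trimesh.creation.icosphere(subdivisions=subdivision, radius=1.0)
    v = np.asarray(ico.vertices)
    return int(np.argmin(v @ v[center_vertex]))


def _default_bumps(structures, subdivision: int) -> dict:
    """AD and MCI-c carry a paired outward/inward bump on every structure.

    Pairing an outward bump with an equal inward bump at the antipodal
    vertex keeps the net volume change zero to first order, so the
    MCI-vs-AD shape effect is orthogonal to volume.
    """
    if not structures:
        return {}
    center = default_bump_center(subdivision)
    anti = antipodal_vertex(subdivision, center)
    per_structure = {
        s: [
            Bump(center, DEFAULT_BUMP_AMPLITUDE[s], DEFAULT_BUMP_WIDTH),
            Bump(anti, -DEFAULT_BUMP_AMPLITUDE[s], DEFAULT_BUMP_WIDTH),
        ]
        for s in structures
        if s in DEFAULT_BUMP_AMPLITUDE
    }
    return {"AD": per_structure, "MCI_c": per_structure}


@dataclass
class SubjectRecord:
    """One subject: diagnosis, CSF triplet, corresponded meshes and volumes."""

    id: str
    group: str
    age: float
    csf: dict          # marker -> pg/mL
    meshes: dict       # structure_tag -> SurfaceMesh
    volumes: dict      # structure_tag -> mm^3


def generate_base_mesh(subdivision: int, semi_axes, structure_tag: str = "synthetic") -> SurfaceMesh:
    """Deterministic closed genus-0 ellipsoid: subdivided icosahedron mapped
    onto the ellipsoid with the given semi-axes (mm)."""
    if subdivision < 1:
        raise ValueError("subdivision must be >= 1")
    a, b, c = semi_axes
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    ico = trimesh.creation.icosphere(subdivisions=subdivision, radius=1.0)
    verts = np.asarray(ico.vertices, dtype=np.float64) * np.array([a, b, c])
    mesh = SurfaceMesh(verts, np.asarray(ico.faces, dtype=np.int64), structure_tag)
    validate_mesh(mesh)
    return mesh


def _sphere_directions(mesh: SurfaceMesh, semi_axes) -> np.ndarray:
    """Unit-sphere preimage directions of an ellipsoid mesh's vertices."""
    d = mesh.vertices / np.asarray(semi_axes)
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def apply_deformation(
    mesh: SurfaceMesh,
    global_scale: float = 1.0,
    bumps: list[Bump] | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    mode_field: np.ndarray | None = None,
) -> SurfaceMesh:
    """Scale about the centroid, add normal-direction bumps, then iid jitter.

    ``mode_field`` is an optional precomputed smooth per-vertex displacement
    (V, 3) added after scaling (used for per-subject anatomical variability).
    Connectivity is shared with the input mesh.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centroid = mesh.vertices.mean(axis=0)
    verts = centroid + global_scale * (mesh.vertices - centroid)
    if mode_field is not None:
        verts = verts + mode_field
    if bumps:
        normals = vertex_normals(mesh)
        dirs = mesh.vertices - centroid
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        for bump in bumps:
            if not 0 <= bump.center_vertex < mesh.n_vertices:
                raise CohortError(
                    f"bump center vertex {bump.center_vertex} out of range "
                    f"for mesh with {mesh.n_vertices} vertices"
                )
            center_dir = dirs[bump.center_vertex]
            theta = np.arccos(np.clip(dirs @ center_dir, -1.0, 1.0))
            profile = bump.amplitude * np.exp(-(theta**2) / (2.0 * bump.width**2))
            verts = verts + profile[:, None] * normals
    if noise_sd > 0:
        verts = verts + rng.normal(0.0, noise_sd, size=verts.shape)
    return mesh.with_vertices(verts)


class _ShapeModeBank:
    """Smooth normal-displacement eigenmodes of a Gaussian kernel on a base mesh.

    The leading eigenvectors of exp(-|x_i - x_j|^2 / (2 w^2)) on the base
    vertices are spherical-harmonic-like smooth scalar fields; per-subject
    anatomy is a random combination of these applied along vertex normals.
    The near-constant leading mode is dropped so the random modes are
    volume-neutral to first order (size is modelled separately).
    """

    def __init__(self, base: SurfaceMesh, width: float, n_modes: int):
        from scipy.spatial.distance import pdist, squareform

        d2 = squareform(pdist(base.vertices, "sqeuclidean"))
        k = np.exp(-d2 / (2.0 * width**2))
        w, v = np.linalg.eigh(k)
        order = np.argsort(w)[::-1]
        # drop mode 0 (near-uniform inflation)
        idx = order[1 : n_modes + 1]
        self.eigvals = np.clip(w[idx], 0.0, None)
        self.modes = v[:, idx]                      # (V, n_modes), orthonormal
        self.normals = vertex_normals(base)
        self.n_vertices = base.n_vertices

    def sample(self, rng: np.random.Generator, rms: float) -> np.ndarray:
        """Random smooth (V, 3) displacement field with RMS vertex norm ``rms``."""
        sig = np.sqrt(self.eigvals)
        q = rng.normal(size=len(sig)) * sig
        scalar = self.modes @ q                     # (V,)
        # E[mean(scalar^2)] = sum(sig^2)/V; rescale to the requested RMS
        expected = np.sqrt(self.eigvals.sum() / self.n_vertices)
        scalar = scalar * (rms / expected)
        return scalar[:, None] * self.normals


def _subject_rng(seed: int, group_index: int, subject_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(seed, spawn_key=(group_index, subject_index))
    return np.random.default_rng(ss)


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a full cohort of :class:`SubjectRecord` from a :class:`CohortSpec`.

    Deterministic given ``spec.seed``; every mesh of a structure shares the
    base mesh's triangle array object.
    """
    if spec.total == 0:
        raise CohortError("all group sizes are zero")
    bases = {
        s: generate_base_mesh(spec.subdivision, spec.semi_axes[s], s)
        for s in spec.structures
    }
    banks = {}
    if spec.structures and (spec.shape_mode_sd > 0):
        banks = {
            s: _ShapeModeBank(bases[s], spec.shape_mode_width, spec.n_shape_modes)
            for s in spec.structures
        }
    records: list[SubjectRecord] = []
    counter = 0
    for gi, group in enumerate(GROUPS):
        n = spec.group_sizes.get(group, 0)
        for si in range(n):
            rng = _subject_rng(spec.seed, gi, si)
            counter += 1
            age_mu, age_sd = spec.age_mean_sd[group]
            age = float(rng.normal(age_mu, age_sd))
            csf = {}
            for marker in CSF_MARKERS:
                mu, sd = spec.csf_params[group][marker]
                csf[marker] = float(max(rng.normal(mu, sd), 1.0))
            meshes, volumes = {}, {}
            for s in spec.structures:
                scale = spec.volume_effect[group][s]
                if spec.scale_jitter_sd > 0:
                    scale = scale * (1.0 + rng.normal(0.0, spec.scale_jitter_sd))
                field = banks[s].sample(rng, spec.shape_mode_sd) if s in banks else None
                bumps = (spec.bump_effect.get(group) or {}).get(s)
                m = apply_deformation(
                    bases[s],
                    global_scale=scale,
                    bumps=bumps,
                    noise_sd=spec.vertex_noise_sd,
                    seed=rng,
                    mode_field=field,
                )
                meshes[s] = m
                volumes[s] = mesh_volume(m)
            records.append(
                SubjectRecord(
                    id=f"S{counter:04d}",
                    group=group,
                    age=age,
                    csf=csf,
                    meshes=meshes,
                    volumes=volumes,
                )
            )
    return records


# ---------------------------------------------------------------------------
# cohort manifest I/O
# ---------------------------------------------------------------------------

def cohort_table(cohort: list[SubjectRecord]) -> pd.DataFrame:
    """Per-subject manifest: id, group, age, CSF markers, structure volumes."""
    rows = []
    for r in cohort:
        row = {"subject_id": r.id, "group": r.group, "age": r.age, **r.csf}
        row.update({f"volume_{s}": v for s, v in r.volumes.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(cohort: list[SubjectRecord], out_dir, mesh_format: str = "off") -> None:
    """Write manifest.csv plus one mesh file per subject per structure."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_table(cohort).to_csv(out / "manifest.csv", index=False)
    for r in cohort:
        for s, mesh in r.meshes.items():
            mesh_core.write_mesh(mesh, out / f"{r.id}_{s}.{mesh_format}")


def read_cohort(in_dir, mesh_format: str = "off") -> list[SubjectRecord]:
    """Read a cohort written by :func:`write_cohort`."""
    src = Path(in_dir)
    table = pd.read_csv(src / "manifest.csv")
    records = []
    for _, row in table.iterrows():
        meshes, volumes = {}, {}
        for s in STRUCTURES:
            p = src / f"{row.subject_id}_{s}.{mesh_format}"
            if p.exists():
                meshes[s] = mesh_core.read_mesh(p, structure_tag=s)
                volumes[s] = mesh_volume(meshes[s])
        records.append(
            SubjectRecord(
                id=row.subject_id,
                group=row.group,
                age=float(row.age),
                csf={m: float(row[m]) for m in CSF_MARKERS},
                meshes=meshes,
                volumes=volumes,
            )
        )
    return records
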