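"""Build a template mesh from optimized vertex locations.

The initial triangulation is the convex hull of the vertex locations on the
registration sphere.  Face connectivity is then improved by diagonal flips:
each pair of neighboring faces forms a quadrilateral ABCD with the shared
edge as one diagonal; the quadrilateral is re-split along whichever diagonal
is shorter *on the anatomy* (straight-line distance between the anchored
anatomical positions), so triangles track the folded geometry rather than
the sphere.  Finally faces are ordered so their normals point outward.
Flips change connectivity only, never vertex locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull

from . import io as surf_io
from .io import Cohort
from .mesh import TriangleMesh, interpolate
from .sampling import CandidateSet, SamplingState

__all__ = [
    "initial_triangulation",
    "flip_pass",
    "optimize_faces",
    "orient_faces",
    "signed_volume",
    "Template",
    "emit_template",
    "anchor_coordinates",
]


def initial_triangulation(points: np.ndarray) -> TriangleMesh:
    """Triangulate points on a sphere as the simplices of their convex hull."""
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 4:
        raise ValueError("need at least 4 points")
    hull = ConvexHull(points)
    if len(hull.vertices) != len(points):
        raise ValueError(
            f"{len(points) - len(hull.vertices)} points are not hull vertices; "
            "input is not in convex position on the sphere"
        )
    return TriangleMesh(points, hull.simplices.astype(np.int64))


def _edge_face_map(faces: np.ndarray) -> dict[tuple[int, int], list[int]]:
    out: dict[tuple[int, int], list[int]] = {}
    for f, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            out.setdefault(key, []).append(f)
    return out


def flip_pass(mesh: TriangleMesh, anat_coords: np.ndarray) -> tuple[TriangleMesh, int]:
    """One deterministic pass of diagonal flips on anatomical edge lengths.

    For each shared edge AC with opposite vertices B and D: if |BD| < |AC|
    on the anatomy, replace faces ABC/ACD by ABD/CBD.  Flips are skipped
    when the alternative diagonal already exists as an edge, when the
    quadrilateral is degenerate, or when a flip would drop an endpoint's
    valence below 3.  Edges are visited in ascending (min, max) order.
    """
    anat_coords = np.asarray(anat_coords, dtype=np.float64)
    faces = [tuple(f) for f in mesh.faces]
    edge_faces = _edge_face_map(mesh.faces)
    valence: dict[int, int] = {}
    for u, v in edge_faces:
        valence[u] = valence.get(u, 0) + 1
        valence[v] = valence.get(v, 0) + 1
    n_incident = np.zeros(mesh.n_vertices, dtype=np.int64)
    np.add.at(n_incident, mesh.faces.ravel(), 1)
    # interior vertices (closed neighborhoods) must keep valence >= 3
    interior = {v: n_incident[v] == deg for v, deg in valence.items()}

    def length(u: int, v: int) -> float:
        return float(np.linalg.norm(anat_coords[u] - anat_coords[v]))

    n_flips = 0
    for edge in sorted(edge_faces.keys()):
        fl = edge_faces.get(edge)
        if fl is None or len(fl) != 2:
            continue
        f1, f2 = fl
        a, c = edge
        tri1, tri2 = faces[f1], faces[f2]
        b = next(v for v in tri1 if v not in edge)
        d = next(v for v in tri2 if v not in edge)
        if b == d or len({a, b, c, d}) != 4:
            continue
        alt = (b, d) if b < d else (d, b)
        if alt in edge_faces:  # the other diagonal is already a mesh edge
            continue
        if length(b, d) >= length(a, c):  # ties keep the current diagonal
            continue
        if (interior.get(a) and valence[a] <= 3) or (interior.get(c) and valence[c] <= 3):
            continue
        new1, new2 = (a, b, d), (c, b, d)
        # rewire bookkeeping
        for f_old, tri_old, tri_new in ((f1, tri1, new1), (f2, tri2, new2)):
            faces[f_old] = tri_new
        del edge_faces[edge]
        valence[a] -= 1
        valence[c] -= 1
        edge_faces[alt] = [f1, f2]
        valence[b] += 1
        valence[d] += 1
        for u, v, f_old, f_new in ((a, d, f2, f1), (c, b, f1, f2)):
            key = (u, v) if u < v else (v, u)
            members = edge_faces[key]
            members[members.index(f_old)] = f_new
        n_flips += 1
    out = TriangleMesh(mesh.coordinates.copy(), np.array(faces, dtype=np.int64))
    return out, n_flips


def total_edge_length(mesh: TriangleMesh, anat_coords: np.ndarray) -> float:
    e = mesh.edges()
    return float(np.linalg.norm(anat_coords[e[:, 0]] - anat_coords[e[:, 1]], axis=1).sum())


def optimize_faces(
    mesh: TriangleMesh, anat_coords: np.ndarray, max_passes: int = 100
) -> TriangleMesh:
    """Repeat flip passes until no flip improves any quadrilateral.

    Total anatomical edge length is non-increasing across passes (each flip
    strictly shortens one diagonal).  Revisiting a previous configuration
    stops the loop with a warning.
    """
    seen = {hash(frozenset(tuple(sorted(f)) for f in mesh.faces))}
    for _ in range(max_passes):
        mesh, n_flips = flip_pass(mesh, anat_coords)
        if n_flips == 0:
            return mesh
        key = hash(frozenset(tuple(sorted(f)) for f in mesh.faces))
        if key in seen:
            warnings.warn("face optimization revisited a configuration; stopping", stacklevel=2)
            return mesh
        seen.add(key)
    warnings.warn(f"face optimization stopped after {max_passes} passes", stacklevel=2)
    return mesh


def orient_faces(mesh: TriangleMesh) -> TriangleMesh:
    """Order each face so its normal points away from the mesh centroid.

    For the star-shaped sphere meshes produced here this yields a
    consistent outward orientation (positive signed volume).
    """
    centroid = mesh.coordinates.mean(axis=0)
    a, b, c = (mesh.coordinates[mesh.faces[:, k]] for k in range(3))
    n = np.cross(b - a, c - a)
    outward = np.einsum("fd,fd->f", n, (a + b + c) / 3.0 - centroid)
    faces = mesh.faces.copy()
    flip = outward < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return TriangleMesh(mesh.coordinates.copy(), faces)


def signed_volume(mesh: TriangleMesh) -> float:
    """Divergence-theorem volume; positive iff faces are oriented outward."""
    a, b, c = (mesh.coordinates[mesh.faces[:, k]] for k in range(3))
    return float(np.einsum("fd,fd->f", a, np.cross(b, c)).sum() / 6.0)


# ---------------------------------------------------------------------------
# Template assembly


def anchor_coordinates(state: SamplingState, candidates: CandidateSet) -> np.ndarray:
    """Per-subject anatomical coordinates of the template anchors, (S, N, 3)."""
    return np.stack(
        [
            interpolate(anat, candidates.sphere.faces, state.anchor_faces, state.anchor_weights)
            for anat in candidates.anatomy_per_subject
        ]
    )


@dataclass
class Template:
    """An optimized surface template: sphere + cohort-average anatomy."""

    sphere: TriangleMesh
    anatomy: TriangleMesh
    metadata: dict = field(default_factory=dict)

    def save(self, directory: str | Path, fmt: str = "freesurfer") -> None:
        import json

        directory = Path(directory)
        ext = ".surf.gii" if fmt == "gifti" else ""
        surf_io.write_surface(self.sphere, directory / f"template.sphere{ext}", fmt)
        surf_io.write_surface(self.anatomy, directory / f"template.anat{ext}", fmt)
        with open(directory / "template.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)

    @classmethod
    def load(cls, directory: str | Path, fmt: str = "freesurfer") -> "Template":
        import json

        directory = Path(directory)
        ext = ".surf.gii" if fmt == "gifti" else ""
        meta_path = directory / "template.json"
        metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            sphere=surf_io.read_surface(directory / f"template.sphere{ext}", fmt),
            anatomy=surf_io.read_surface(directory / f"template.anat{ext}", fmt),
            metadata=metadata,
        )


def emit_template(
    state: SamplingState,
    candidates: CandidateSet,
    cohort: Cohort,
    max_flip_passes: int = 100,
) -> Template:
    """Assemble the final template from an optimized sampling state.

    Triangulates the anchors' sphere positions, optimizes faces on the
    cohort-average anatomy, orients them outward, and attaches the
    anchors' cohort-average anatomical coordinates.
    """
    per_subject = anchor_coordinates(state, candidates)
    anat_mean = per_subject.mean(axis=0)
    mesh = initial_triangulation(state.positions)
    mesh = orient_faces(mesh)
    mesh = optimize_faces(mesh, anat_mean, max_passes=max_flip_passes)
    mesh = orient_faces(mesh)
    sphere = TriangleMesh(state.positions.copy(), mesh.faces)
    anatomy = TriangleMesh(anat_mean, mesh.faces.copy())
    metadata = {
        "n_vertices": int(state.n),
        "template_ico": int(candidates.template_ico),
        "loss": float(state.loss),
        "stage": state.stage,
        "n_subjects": len(cohort),
    }
    return Template(sphere=sphere, anatomy=anatomy, metadata=metadata)
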