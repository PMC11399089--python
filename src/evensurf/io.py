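"""Surface and per-vertex map I/O (FreeSurfer binary, GIFTI) and cohorts.

A *cohort* is a set of subjects whose spherical registration surface and
folded anatomical surface share a single topology, so that vertex i refers
to the same macroanatomical location in every brain.  The cohort's average
anatomical metric (mean edge lengths across subjects) is the substrate on
which template vertices are placed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import nibabel as nib
import numpy as np
import scipy.sparse as sp

from .mesh import MeshError, TriangleMesh, edge_graph

__all__ = [
    "SurfaceFormatError",
    "SubjectSurface",
    "Cohort",
    "read_surface",
    "write_surface",
    "read_vertex_map",
    "write_vertex_map",
    "average_surfaces",
    "cohort_mean_edge_lengths",
    "load_cohort",
    "save_cohort",
]


class SurfaceFormatError(IOError):
    """Raised when a surface file cannot be parsed."""


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("freesurfer", "gifti"):
            raise ValueError(f"unknown surface format {fmt!r}")
        return fmt
    return "gifti" if str(path).endswith(".gii") else "freesurfer"


def read_surface(path: str | Path, fmt: str | None = None) -> TriangleMesh:
    """Read a surface mesh (FreeSurfer binary or GIFTI ``.surf.gii``).

    The format is inferred from the extension unless given.  The mesh is
    validated as a closed genus-0 surface; coordinates are in mm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    try:
        if fmt == "freesurfer":
            coords, faces = nib.freesurfer.io.read_geometry(str(path))
        else:
            img = nib.load(str(path))
            coords = img.agg_data("NIFTI_INTENT_POINTSET")
            faces = img.agg_data("NIFTI_INTENT_TRIANGLE")
    except (ValueError, OSError, KeyError) as exc:
        raise SurfaceFormatError(f"cannot parse {fmt} surface {path}: {exc}") from exc
    mesh = TriangleMesh(np.asarray(coords, dtype=np.float64), np.asarray(faces, dtype=np.int64))
    try:
        mesh.validate()
    except MeshError as exc:
        raise MeshError(f"{path}: {exc}") from exc
    return mesh


def write_surface(mesh: TriangleMesh, path: str | Path, fmt: str | None = None) -> None:
    """Write a surface mesh; round-trips with :func:`read_surface` at float32."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    os.makedirs(path.parent, exist_ok=True)
    if fmt == "freesurfer":
        nib.freesurfer.io.write_geometry(str(path), mesh.coordinates, mesh.faces)
    else:
        darrays = [
            nib.gifti.GiftiDataArray(
                mesh.coordinates.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            ),
            nib.gifti.GiftiDataArray(
                mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            ),
        ]
        nib.save(nib.gifti.GiftiImage(darrays=darrays), str(path))


def read_vertex_map(path: str | Path, fmt: str | None = None) -> np.ndarray:
    """Read a per-vertex scalar map (FreeSurfer curv or GIFTI ``.shape.gii``)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    try:
        if fmt == "freesurfer":
            return np.asarray(nib.freesurfer.io.read_morph_data(str(path)), dtype=np.float64)
        img = nib.load(str(path))
        return np.asarray(img.darrays[0].data, dtype=np.float64)
    except (ValueError, OSError) as exc:
        raise SurfaceFormatError(f"cannot parse {fmt} map {path}: {exc}") from exc


def write_vertex_map(values: np.ndarray, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    os.makedirs(path.parent, exist_ok=True)
    values = np.asarray(values, dtype=np.float32)
    if fmt == "freesurfer":
        nib.freesurfer.io.write_morph_data(str(path), values)
    else:
        da = nib.gifti.GiftiDataArray(values, intent="NIFTI_INTENT_SHAPE")
        nib.save(nib.gifti.GiftiImage(darrays=[da]), str(path))


# ---------------------------------------------------------------------------
# Subjects and cohorts


@dataclass
class SubjectSurface:
    """A subject's registration sphere and anatomical surface, shared topology."""

    subject_id: str
    sphere: TriangleMesh
    anatomy: TriangleMesh

    def __post_init__(self):
        if self.sphere.n_vertices != self.anatomy.n_vertices or not np.array_equal(
            self.sphere.faces, self.anatomy.faces
        ):
            raise ValueError(f"{self.subject_id}: sphere and anatomy topology differ")
        r = np.linalg.norm(self.sphere.coordinates, axis=1)
        rmean = r.mean()
        if rmean <= 0 or np.max(np.abs(r - rmean)) > 1e-3 * rmean:
            raise ValueError(f"{self.subject_id}: registration surface is not a sphere")

    @property
    def sphere_radius(self) -> float:
        return float(np.linalg.norm(self.sphere.coordinates, axis=1).mean())


@dataclass
class Cohort:
    """Subjects sharing one mesh topology, with a cohort-average edge metric."""

    subjects: list[SubjectSurface] = field(default_factory=list)

    def __post_init__(self):
        if not self.subjects:
            raise ValueError("cohort needs at least one subject")
        f0 = self.subjects[0].sphere.faces
        for s in self.subjects[1:]:
            if not np.array_equal(s.sphere.faces, f0):
                raise ValueError(f"{s.subject_id}: face list differs from cohort topology")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def faces(self) -> np.ndarray:
        return self.subjects[0].sphere.faces

    @property
    def n_vertices(self) -> int:
        return self.subjects[0].sphere.n_vertices

    @property
    def sphere_radius(self) -> float:
        return self.subjects[0].sphere_radius

    @cached_property
    def edges(self) -> np.ndarray:
        return self.subjects[0].sphere.edges()

    @cached_property
    def mean_edge_lengths(self) -> np.ndarray:
        return cohort_mean_edge_lengths(self)

    def mean_edge_graph(self) -> sp.csr_matrix:
        """Vertex graph weighted by cohort-mean anatomical edge lengths."""
        return edge_graph(self.subjects[0].anatomy, lengths=self.mean_edge_lengths)


def average_surfaces(meshes: list[TriangleMesh]) -> TriangleMesh:
    """Vertex-wise arithmetic mean of surfaces sharing one topology."""
    if not meshes:
        raise ValueError("need at least one mesh")
    f0 = meshes[0].faces
    for m in meshes[1:]:
        if not np.array_equal(m.faces, f0):
            raise ValueError("topology mismatch in average_surfaces")
    coords = np.mean([m.coordinates for m in meshes], axis=0)
    return TriangleMesh(coords, f0.copy())


def cohort_mean_edge_lengths(cohort: Cohort) -> np.ndarray:
    """Per-edge anatomical length (mm), averaged across the cohort's subjects."""
    e = cohort.edges
    total = np.zeros(len(e))
    for s in cohort.subjects:
        c = s.anatomy.coordinates
        total += np.linalg.norm(c[e[:, 0]] - c[e[:, 1]], axis=1)
    return total / len(cohort)


def load_cohort(directory: str | Path, fmt: str = "freesurfer") -> Cohort:
    """Load a cohort written by :func:`save_cohort` (``<sub>.sphere``/``<sub>.anat``)."""
    directory = Path(directory)
    ext = ".surf.gii" if fmt == "gifti" else ""
    subjects = []
    for sphere_path in sorted(directory.glob(f"*.sphere{ext}")):
        sid = sphere_path.name.split(".sphere")[0]
        anat_path = directory / f"{sid}.anat{ext}"
        if not anat_path.exists():
            raise FileNotFoundError(anat_path)
        subjects.append(
            SubjectSurface(sid, read_surface(sphere_path), read_surface(anat_path))
        )
    if not subjects:
        raise FileNotFoundError(f"no '*.sphere{ext}' surfaces in {directory}")
    return Cohort(subjects)


def save_cohort(cohort: Cohort, directory: str | Path, fmt: str = "freesurfer") -> None:
    directory = Path(directory)
    ext = ".surf.gii" if fmt == "gifti" else ""
    for s in cohort.subjects:
        write_surface(s.sphere, directory / f"{s.subject_id}.sphere{ext}", fmt)
        write_surface(s.anatomy, directory / f"{s.subject_id}.anat{ext}", fmt)
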