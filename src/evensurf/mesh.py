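"""Triangle-mesh geometry: icospheres, areas, graph geodesics, barycentric anchors.

The meshes handled here are closed genus-0 triangle surfaces (registration
spheres and folded anatomical surfaces share this topology).  Geodesic
distances are graph geodesics: shortest paths along mesh edges weighted by
Euclidean edge length, computed with Dijkstra's algorithm.  Points that do
not coincide with mesh vertices are represented as barycentric anchors
(face index + convex weights) on a reference mesh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

__all__ = [
    "MeshError",
    "TriangleMesh",
    "BarycentricPoint",
    "Searchlight",
    "make_icosphere",
    "vertex_areas",
    "edge_graph",
    "geodesic_distances",
    "make_searchlight",
    "barycentric_locate",
    "locate_on_mesh",
    "interpolate",
    "estimate_distance",
]


class MeshError(ValueError):
    """Raised when a mesh violates the closed-surface invariants."""


@dataclass
class TriangleMesh:
    """A triangle mesh: per-vertex mm coordinates and ordered faces.

    Faces are 0-based triples of vertex indices.  For a valid closed
    genus-0 surface every edge is shared by exactly two faces and
    V - E + F = 2.
    """

    coordinates: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.coordinates = np.ascontiguousarray(self.coordinates, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise MeshError("coordinates must have shape (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must have shape (F, 3)")

    @property
    def n_vertices(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array with e[:, 0] < e[:, 1]."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        return np.unique(np.sort(e, axis=1), axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces

    def face_areas(self) -> np.ndarray:
        a, b, c = (self.coordinates[self.faces[:, k]] for k in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def face_normals(self, normalize: bool = True) -> np.ndarray:
        a, b, c = (self.coordinates[self.faces[:, k]] for k in range(3))
        n = np.cross(b - a, c - a)
        if normalize:
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            n = n / norm
        return n

    def validate(self) -> None:
        """Check closed-surface invariants; raise :class:`MeshError` on failure."""
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise MeshError("face index out of range")
        e = np.sort(
            np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]),
            axis=1,
        )
        if np.any(e[:, 0] == e[:, 1]):
            raise MeshError("degenerate face with repeated vertex")
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        if np.any(counts != 2):
            n_bad = int(np.sum(counts != 2))
            raise MeshError(
                f"mesh is not a closed surface: {n_bad} edges not shared by exactly 2 faces"
            )
        chi = self.n_vertices - len(uniq) + self.n_faces
        if chi != 2:
            raise MeshError(f"Euler characteristic {chi} != 2 (not genus-0)")
        if np.any(self.face_areas() <= 0):
            raise MeshError("zero-area face")

    def scaled(self, factor: float) -> "TriangleMesh":
        return TriangleMesh(self.coordinates * factor, self.faces)


@dataclass
class BarycentricPoint:
    """A point anchored on a mesh face by convex barycentric weights."""

    face: int
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (3,):
            raise ValueError("weights must have shape (3,)")
        if np.any(self.weights < -1e-9) or abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("barycentric weights must be nonnegative and sum to 1")
        self.weights = np.clip(self.weights, 0.0, None)
        self.weights /= self.weights.sum()


@dataclass
class Searchlight:
    """Vertices within a geodesic radius of a center vertex."""

    center: int
    radius: float
    members: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Icosphere construction

_PHI = (1.0 + np.sqrt(5.0)) / 2.0

_ICO_VERTICES = np.array(
    [
        (-1, _PHI, 0), (1, _PHI, 0), (-1, -_PHI, 0), (1, -_PHI, 0),
        (0, -1, _PHI), (0, 1, _PHI), (0, -1, -_PHI), (0, 1, -_PHI),
        (_PHI, 0, -1), (_PHI, 0, 1), (-_PHI, 0, -1), (-_PHI, 0, 1),
    ],
    dtype=np.float64,
)

_ICO_FACES = np.array(
    [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ],
    dtype=np.int64,
)


def make_icosphere(ico_order: int, radius: float = 1.0) -> TriangleMesh:
    """Geodesic icosahedron of the given subdivision frequency.

    Each icosahedron edge is split into ``ico_order`` equal segments and the
    resulting planar grid points are projected radially onto the sphere,
    giving ``10 * ico_order**2 + 2`` vertices and ``20 * ico_order**2``
    faces.  ``ico_order`` is the "ico" resolution convention (ico32 has
    10,242 vertices).
    """
    if not float(ico_order).is_integer() or ico_order < 1:
        raise ValueError(f"ico_order must be a positive integer, got {ico_order!r}")
    n = int(ico_order)
    base_v = _ICO_VERTICES / np.linalg.norm(_ICO_VERTICES, axis=1, keepdims=True)
    if n == 1:
        return TriangleMesh(base_v * radius, _ICO_FACES.copy())

    e = np.sort(np.vstack([_ICO_FACES[:, [0, 1]], _ICO_FACES[:, [1, 2]], _ICO_FACES[:, [2, 0]]]), axis=1)
    edges = np.unique(e, axis=0)  # (30, 2), canonical u < v
    edge_id = {(int(u), int(v)): k for k, (u, v) in enumerate(edges)}

    n_edge_pts = n - 1
    n_int = (n - 1) * (n - 2) // 2
    n_vertices = 12 + 30 * n_edge_pts + 20 * n_int
    coords = np.empty((n_vertices, 3), dtype=np.float64)
    coords[:12] = base_v
    # interior points of each edge, ordered from the lower- to the
    # higher-index endpoint
    t = (np.arange(1, n, dtype=np.float64) / n)[None, :, None]
    ea = base_v[edges[:, 0]][:, None, :]
    eb = base_v[edges[:, 1]][:, None, :]
    coords[12:12 + 30 * n_edge_pts] = (ea * (1 - t) + eb * t).reshape(-1, 3)
    int_base = 12 + 30 * n_edge_pts

    def edge_interior(u: int, v: int) -> np.ndarray:
        """Global indices of edge-interior points ordered along u -> v."""
        if u < v:
            eid = edge_id[(u, v)]
            return 12 + eid * n_edge_pts + np.arange(n_edge_pts)
        eid = edge_id[(v, u)]
        return 12 + eid * n_edge_pts + np.arange(n_edge_pts - 1, -1, -1)

    if n_int > 0:
        gi0, gj0 = np.meshgrid(np.arange(1, n), np.arange(1, n), indexing="ij")
        int_mask = (gi0 + gj0) <= n - 1
        gi, gj = gi0[int_mask], gj0[int_mask]

    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    up_mask = (ii + jj) <= n - 1
    dn_mask = (ii + jj) <= n - 2
    ui, uj = ii[up_mask], jj[up_mask]
    di, dj = ii[dn_mask], jj[dn_mask]

    faces_out = np.empty((20 * n * n, 3), dtype=np.int64)
    fpos = 0
    for fidx, (a, b, c) in enumerate(_ICO_FACES):
        grid = np.full((n + 1, n + 1), -1, dtype=np.int64)
        grid[0, 0], grid[n, 0], grid[0, n] = a, b, c
        grid[1:n, 0] = edge_interior(a, b)
        grid[0, 1:n] = edge_interior(a, c)
        bc = edge_interior(b, c)  # ordered b -> c; grid point (i, n-i) is step n-i from b
        steps = np.arange(1, n)
        grid[n - steps, steps] = bc[steps - 1]
        if n_int > 0:
            idx = int_base + fidx * n_int + np.arange(n_int)
            grid[gi, gj] = idx
            A, B, C = base_v[a], base_v[b], base_v[c]
            coords[idx] = (
                A[None, :]
                + (gi / n)[:, None] * (B - A)[None, :]
                + (gj / n)[:, None] * (C - A)[None, :]
            )
        nf_up = len(ui)
        faces_out[fpos:fpos + nf_up, 0] = grid[ui, uj]
        faces_out[fpos:fpos + nf_up, 1] = grid[ui + 1, uj]
        faces_out[fpos:fpos + nf_up, 2] = grid[ui, uj + 1]
        fpos += nf_up
        nf_dn = len(di)
        faces_out[fpos:fpos + nf_dn, 0] = grid[di + 1, dj]
        faces_out[fpos:fpos + nf_dn, 1] = grid[di + 1, dj + 1]
        faces_out[fpos:fpos + nf_dn, 2] = grid[di, dj + 1]
        fpos += nf_dn

    coords *= radius / np.linalg.norm(coords, axis=1, keepdims=True)
    return TriangleMesh(coords, faces_out)


# ---------------------------------------------------------------------------
# Areas and graphs


def vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex area: one third of the area of all incident faces (mm^2).

    The sum over vertices equals the total surface area exactly.
    """
    fa = mesh.face_areas()
    if np.any(fa == 0):
        warnings.warn("degenerate (zero-area) faces contribute nothing", stacklevel=2)
    out = np.zeros(mesh.n_vertices)
    contrib = np.repeat(fa / 3.0, 3)
    np.add.at(out, mesh.faces.ravel(), contrib)
    return out


def edge_graph(mesh: TriangleMesh, lengths: np.ndarray | None = None) -> sp.csr_matrix:
    """Symmetric sparse vertex adjacency weighted by edge length (mm).

    ``lengths`` overrides the Euclidean lengths computed from the mesh's own
    coordinates (one value per edge of ``mesh.edges()``); this is how a
    cohort-average anatomical metric is attached to a shared topology.
    """
    e = mesh.edges()
    if lengths is None:
        lengths = np.linalg.norm(
            mesh.coordinates[e[:, 0]] - mesh.coordinates[e[:, 1]], axis=1
        )
    else:
        lengths = np.asarray(lengths, dtype=np.float64)
        if lengths.shape != (len(e),):
            raise ValueError("lengths must have one entry per mesh edge")
    if np.any(lengths <= 0):
        raise MeshError("nonpositive edge length")
    n = mesh.n_vertices
    g = sp.coo_matrix(
        (np.concatenate([lengths, lengths]),
         (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(n, n),
    ).tocsr()
    n_comp, _ = connected_components(g, directed=False)
    if n_comp != 1:
        raise MeshError(f"mesh graph is disconnected ({n_comp} components)")
    return g


def geodesic_distances(
    graph: sp.spmatrix, source: int, cutoff: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Dijkstra shortest-path distances (mm) from ``source`` along mesh edges.

    Returns ``(vertices, distances)`` for all vertices reachable within
    ``cutoff`` (inclusive); with ``cutoff=None`` the full row is returned.
    ``d(source, source) == 0`` is always included.
    """
    n = graph.shape[0]
    if not 0 <= source < n:
        raise ValueError(f"source {source} out of range for {n} vertices")
    limit = np.inf if cutoff is None else float(cutoff)
    row = dijkstra(graph, directed=False, indices=[source], limit=limit)[0]
    mask = row <= limit
    idx = np.flatnonzero(mask)
    return idx, row[idx]


def make_searchlight(graph: sp.spmatrix, center: int, radius: float) -> Searchlight:
    """All vertices within geodesic ``radius`` (inclusive) of ``center``."""
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    idx, _ = geodesic_distances(graph, center, cutoff=radius)
    return Searchlight(center=int(center), radius=float(radius), members=idx)


# ---------------------------------------------------------------------------
# Barycentric anchors


class _CentralLocator:
    """Locates directions on a star-shaped (spherical) mesh by central projection.

    For a face with corner matrix M = [A B C] (columns) and query point p,
    solving M u = p gives the intersection of the ray through p with the
    face plane at barycentric coordinates u / sum(u); the ray hits the face
    iff all components of u are nonnegative.
    """

    def __init__(self, mesh: TriangleMesh):
        self.mesh = mesh
        corners = mesh.coordinates[mesh.faces]  # (F, 3, 3) rows=corners
        self._inv = np.linalg.inv(np.swapaxes(corners, 1, 2))  # inverse of column matrices
        self._tree = cKDTree(mesh.coordinates)
        # padded vertex -> incident faces table
        counts = np.zeros(mesh.n_vertices, dtype=np.int64)
        np.add.at(counts, mesh.faces.ravel(), 1)
        maxdeg = int(counts.max())
        table = np.full((mesh.n_vertices, maxdeg), -1, dtype=np.int64)
        flat = mesh.faces.ravel()
        order = np.argsort(flat, kind="stable")
        verts_sorted = flat[order]
        face_of = order // 3
        starts = np.zeros(mesh.n_vertices, dtype=np.int64)
        starts[1:] = np.cumsum(counts)[:-1]
        slot = np.arange(len(flat)) - starts[verts_sorted]
        table[verts_sorted, slot] = face_of
        self._vertex_faces = table

    def locate(self, points: np.ndarray, tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        norms = np.linalg.norm(points, axis=1)
        if np.any(norms == 0):
            raise ValueError("cannot locate the zero vector on a sphere mesh")
        _, nearest = self._tree.query(points)
        cand = self._vertex_faces[nearest]  # (P, K)
        safe = np.where(cand >= 0, cand, 0)
        u = np.einsum("pkij,pj->pki", self._inv[safe], points)
        s = u.sum(axis=2)
        ok = (cand >= 0) & (u.min(axis=2) >= -tol * np.maximum(1.0, np.abs(s))) & (s > 0)
        # lowest face index among acceptable candidates (deterministic ties)
        big = np.iinfo(np.int64).max
        masked = np.where(ok, cand, big)
        pick = masked.argmin(axis=1)
        faces = masked[np.arange(len(points)), pick]
        weights = np.empty((len(points), 3))
        good = faces != big
        if np.any(good):
            ug = u[np.arange(len(points)), pick][good]
            weights[good] = np.clip(ug / ug.sum(axis=1, keepdims=True), 0.0, None)
            weights[good] /= weights[good].sum(axis=1, keepdims=True)
        if not np.all(good):  # rare fallback: scan all faces
            for i in np.flatnonzero(~good):
                ui = self._inv @ points[i]
                si = ui.sum(axis=1)
                score = np.where(si > 0, ui.min(axis=1) / np.maximum(si, 1e-300), -np.inf)
                f = int(np.argmax(score))
                faces[i] = f
                w = np.clip(ui[f] / ui[f].sum(), 0.0, None)
                weights[i] = w / w.sum()
        return faces.astype(np.int64), weights


_LOCATOR_CACHE: dict[int, _CentralLocator] = {}


def _get_locator(mesh: TriangleMesh) -> _CentralLocator:
    key = id(mesh)
    loc = _LOCATOR_CACHE.get(key)
    if loc is None or loc.mesh is not mesh:
        loc = _CentralLocator(mesh)
        _LOCATOR_CACHE.clear()  # keep at most one; meshes here are large
        _LOCATOR_CACHE[key] = loc
    return loc


def locate_on_mesh(mesh: TriangleMesh, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batch barycentric location by central projection.

    Returns ``(faces, weights)`` arrays for an (P, 3) array of points on or
    near a star-shaped mesh (any nonzero direction for sphere meshes).
    """
    return _get_locator(mesh).locate(points)


def barycentric_locate(mesh: TriangleMesh, point: np.ndarray) -> BarycentricPoint:
    """Locate a single point on the mesh; see :func:`locate_on_mesh`."""
    faces, weights = locate_on_mesh(mesh, np.asarray(point, dtype=np.float64)[None, :])
    return BarycentricPoint(face=int(faces[0]), weights=weights[0])


def interpolate(mesh_coords: np.ndarray, faces: np.ndarray,
                anchor_faces: np.ndarray, anchor_weights: np.ndarray) -> np.ndarray:
    """Evaluate barycentric anchors against any coordinate set sharing the topology."""
    corner_idx = faces[anchor_faces]  # (P, 3)
    return np.einsum("pkd,pk->pd", mesh_coords[corner_idx], anchor_weights)


def estimate_distance(
    p_i: BarycentricPoint, p_j: BarycentricPoint, node_distances: np.ndarray
) -> float:
    """Barycentric estimate of the geodesic distance between two anchored points.

    ``node_distances`` is the 3x3 matrix of geodesic distances between the
    corners of ``p_i``'s face (rows) and ``p_j``'s face (columns); the
    estimate is the double-weighted sum ``sum_kl w_ik w_jl d_kl``.  It is
    exact when both anchors sit on mesh vertices.
    """
    d = np.asarray(node_distances, dtype=np.float64)
    if d.shape != (3, 3):
        raise ValueError("node_distances must be a 3x3 matrix")
    if np.any(~np.isfinite(d)):
        raise ValueError("node_distances contains missing (non-finite) corner distances")
    return float(p_i.weights @ d @ p_j.weights)
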