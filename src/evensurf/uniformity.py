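"""Template evaluation: vertex-density maps, dispersion, and runtime scaling.

Three per-vertex properties quantify local sampling density: the mean
distance to mesh neighbors (averaged across cohort subjects), the vertex
area (a third of the incident face areas), and the number of vertices in a
20-mm geodesic searchlight.  A uniformly sampling template minimizes the
dispersion of all three across the cortex.  The runtime model fits
``time ~ size^p`` in log-log space, the scaling that makes oversized
searchlights disproportionately expensive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .io import Cohort
from .mesh import TriangleMesh, edge_graph, interpolate, locate_on_mesh, vertex_areas

__all__ = [
    "VertexPropertyMap",
    "DispersionStats",
    "PowerLawFit",
    "template_subject_coordinates",
    "inter_vertex_distance_map",
    "vertex_area_map",
    "searchlight_count_map",
    "evaluate_template",
    "dispersion",
    "variance_reduction",
    "fit_power_law",
    "doubling_factor",
]


@dataclass
class VertexPropertyMap:
    """A named per-vertex scalar property (finite, positive values)."""

    name: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("values must be a nonempty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.name}: non-finite values")


@dataclass
class DispersionStats:
    mean: float
    sd: float
    variance: float
    units: str = ""


@dataclass
class PowerLawFit:
    """y ~ scale * x**exponent, fitted by least squares in log-log space."""

    exponent: float
    scale: float
    fit_range: tuple[float, float]


def dispersion(prop: VertexPropertyMap, ddof: int = 0) -> DispersionStats:
    """Mean / s.d. / variance of a property map (population variance by default)."""
    v = prop.values
    var = float(np.var(v, ddof=ddof))
    return DispersionStats(mean=float(v.mean()), sd=float(np.sqrt(var)), variance=var,
                           units=prop.units)


def variance_reduction(old: DispersionStats, new: DispersionStats) -> float:
    """Percent decrease in variance, 100 * (1 - new/old)."""
    if old.variance <= 0:
        raise ValueError("old variance must be positive")
    return 100.0 * (1.0 - new.variance / old.variance)


# ---------------------------------------------------------------------------
# Template property maps


def template_subject_coordinates(template_sphere: TriangleMesh, cohort: Cohort) -> np.ndarray:
    """Anatomical coordinates of template vertices per subject, (S, N, 3).

    Template sphere vertices are located on each subject's registration
    sphere by central projection and carried to the subject anatomy by
    barycentric interpolation.
    """
    coords = np.empty((len(cohort), template_sphere.n_vertices, 3))
    faces = weights = None
    sphere0 = cohort.subjects[0].sphere
    for s_i, subj in enumerate(cohort.subjects):
        if s_i == 0 or not np.array_equal(subj.sphere.coordinates, sphere0.coordinates):
            faces, weights = locate_on_mesh(subj.sphere, template_sphere.coordinates)
        coords[s_i] = interpolate(subj.anatomy.coordinates, cohort.faces, faces, weights)
    return coords


def inter_vertex_distance_map(
    template: TriangleMesh, subject_coords: np.ndarray
) -> VertexPropertyMap:
    """Mean anchor-to-anchor distance to template-mesh neighbors, over subjects (mm)."""
    e = template.edges()
    n = template.n_vertices
    deg = np.zeros(n)
    np.add.at(deg, e[:, 0], 1)
    np.add.at(deg, e[:, 1], 1)
    if np.any(deg == 0):
        raise ValueError("template mesh has isolated vertices")
    total = np.zeros(n)
    for coords in subject_coords:
        lengths = np.linalg.norm(coords[e[:, 0]] - coords[e[:, 1]], axis=1)
        np.add.at(total, e[:, 0], lengths)
        np.add.at(total, e[:, 1], lengths)
    values = total / (deg * len(subject_coords))
    return VertexPropertyMap("inter_vertex_distance", values, units="mm")


def vertex_area_map(template: TriangleMesh, subject_coords: np.ndarray) -> VertexPropertyMap:
    """Vertex area on the subject anatomies, averaged across subjects (mm^2)."""
    total = np.zeros(template.n_vertices)
    for coords in subject_coords:
        total += vertex_areas(TriangleMesh(coords, template.faces))
    return VertexPropertyMap("vertex_area", total / len(subject_coords), units="mm^2")


def searchlight_count_map(
    template: TriangleMesh, subject_coords: np.ndarray, radius: float = 20.0
) -> VertexPropertyMap:
    """Number of vertices within a geodesic searchlight on the cohort-mean metric.

    The graph is the template mesh with each edge weighted by its mean
    anatomical length across subjects; counts include the center.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    e = template.edges()
    mean_len = np.mean(
        [np.linalg.norm(c[e[:, 0]] - c[e[:, 1]], axis=1) for c in subject_coords], axis=0
    )
    graph = edge_graph(template, lengths=mean_len)
    d = dijkstra(graph, directed=False, limit=radius)
    counts = (d <= radius).sum(axis=1)
    return VertexPropertyMap("searchlight_count", counts.astype(np.float64), units="vertices")


def evaluate_template(
    template_sphere: TriangleMesh, cohort: Cohort, radius: float = 20.0
) -> dict[str, VertexPropertyMap]:
    """All three density maps for a template sphere evaluated against a cohort."""
    coords = template_subject_coordinates(template_sphere, cohort)
    return {
        "inter_vertex_distance": inter_vertex_distance_map(template_sphere, coords),
        "vertex_area": vertex_area_map(template_sphere, coords),
        "searchlight_count": searchlight_count_map(template_sphere, coords, radius=radius),
    }


# ---------------------------------------------------------------------------
# Runtime scaling


def fit_power_law(sizes: np.ndarray, times: np.ndarray) -> PowerLawFit:
    """Least-squares fit of ``times ~ sizes**p`` in log-log space."""
    sizes = np.asarray(sizes, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    if len(sizes) < 2 or len(sizes) != len(times):
        raise ValueError("need at least two (size, time) points")
    if np.any(sizes <= 0) or np.any(times <= 0):
        raise ValueError("sizes and times must be positive")
    slope, intercept = np.polyfit(np.log(sizes), np.log(times), 1)
    return PowerLawFit(exponent=float(slope), scale=float(np.exp(intercept)),
                       fit_range=(float(sizes.min()), float(sizes.max())))


def doubling_factor(fit: PowerLawFit | float) -> float:
    """Runtime multiplier when the problem size doubles: 2**p."""
    p = fit.exponent if isinstance(fit, PowerLawFit) else float(fit)
    if not np.isfinite(p):
        raise ValueError("exponent must be finite")
    return float(2.0**p)
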