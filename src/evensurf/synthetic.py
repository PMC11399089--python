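"""Synthetic cohorts and response data for end-to-end testing without downloads.

The generator emulates the key geometric feature of real registration data:
the anatomical surface is a smooth, per-region expansion/shrinkage of the
registration sphere (the distortion that full inflation introduces), shared
across the population, plus small per-subject jitter.  The radial modulation
``r * exp(alpha * f)`` with a standardized smooth field ``f`` guarantees
positive radii and makes ``alpha`` interpretable as log-scale distortion.

Response matrices for the MVPA benchmark mix a shared signal with
independent noise: ``sqrt(s) * S + sqrt(1 - s) * N_p`` so that the expected
correlation between two participants' patterns equals the signal fraction
``s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import Cohort, SubjectSurface
from .mesh import TriangleMesh, make_icosphere

__all__ = ["DistortionSpec", "ResponseCohort", "make_subject", "make_cohort", "make_responses"]


@dataclass
class DistortionSpec:
    """Parameters of the synthetic sphere-to-anatomy distortion.

    alpha is the dimensionless log-scale distortion amplitude; smooth_passes
    the number of neighbor-averaging passes applied to the i.i.d. field;
    jitter the per-subject per-coordinate normal s.d. in mm; radius the
    registration-sphere radius in mm (100 mm, the FreeSurfer convention).
    """

    ico_order: int = 16
    alpha: float = 0.5
    smooth_passes: int = 4
    jitter: float = 0.2
    radius: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0 or self.jitter < 0 or self.smooth_passes < 0:
            raise ValueError("alpha, jitter, and smooth_passes must be nonnegative")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def _smoothing_operator(mesh: TriangleMesh) -> sp.csr_matrix:
    """Row-normalized (vertex + neighbors) averaging operator."""
    e = mesh.edges()
    n = mesh.n_vertices
    ones = np.ones(len(e))
    adj = sp.coo_matrix(
        (np.concatenate([ones, ones]),
         (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(n, n),
    ).tocsr() + sp.eye(n, format="csr")
    inv_deg = 1.0 / np.asarray(adj.sum(axis=1)).ravel()
    return sp.diags(inv_deg) @ adj

def distortion_field(spec: DistortionSpec, sphere: TriangleMesh) -> np.ndarray:
    """The population's standardized smooth log-distortion field."""
    rng = np.random.default_rng(spec.seed)
    f = rng.standard_normal(sphere.n_vertices)
    if spec.smooth_passes > 0:
        op = _smoothing_operator(sphere)
        for _ in range(spec.smooth_passes):
            f = op @ f
    f = f - f.mean()
    sd = f.std()
    if sd > 0:
        f = f / sd
    return f


def _apply_distortion(
    sphere: TriangleMesh, f: np.ndarray, spec: DistortionSpec, jitter_rng: np.random.Generator
) -> TriangleMesh:
    scale = np.exp(spec.alpha * f)
    coords = sphere.coordinates * scale[:, None]
    if spec.jitter > 0:
        coords = coords + spec.jitter * jitter_rng.standard_normal(coords.shape)
    return TriangleMesh(coords, sphere.faces.copy())


def make_subject(spec: DistortionSpec, subject_seed: int, subject_id: str | None = None) -> SubjectSurface:
    """One synthetic subject: icosphere registration surface + distorted anatomy.

    The distortion field is a pure function of ``spec.seed`` (the population
    anatomy); the jitter is a pure function of ``subject_seed``.
    """
    sphere = make_icosphere(spec.ico_order, radius=spec.radius)
    f = distortion_field(spec, sphere)
    anatomy = _apply_distortion(sphere, f, spec, np.random.default_rng(subject_seed))
    return SubjectSurface(subject_id or f"sub-{subject_seed}", sphere, anatomy)


def make_cohort(spec: DistortionSpec, n_subjects: int) -> Cohort:
    """A cohort sharing one population distortion field, with per-subject jitter."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    sphere = make_icosphere(spec.ico_order, radius=spec.radius)
    f = distortion_field(spec, sphere)
    seeds = np.random.SeedSequence(spec.seed).spawn(n_subjects)
    subjects = []
    for i, ss in enumerate(seeds):
        anatomy = _apply_distortion(sphere, f, spec, np.random.default_rng(ss))
        subjects.append(SubjectSurface(f"sub-{i:03d}", sphere, anatomy))
    return Cohort(subjects)


@dataclass
class ResponseCohort:
    """Per-participant (time points x vertices) matrices with shared signal."""

    data: list[np.ndarray] = field(default_factory=list)
    signal_fraction: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        shapes = {m.shape for m in self.data}
        if len(shapes) > 1:
            raise ValueError("all participant matrices must share a shape")

    @property
    def n_participants(self) -> int:
        return len(self.data)

    @property
    def n_timepoints(self) -> int:
        return self.data[0].shape[0]


def make_responses(
    n_participants: int,
    n_timepoints: int,
    n_vertices: int,
    signal_fraction: float,
    seed: int = 0,
) -> ResponseCohort:
    """Synthetic multi-participant responses with a controlled shared-signal fraction."""
    if not 0.0 <= signal_fraction <= 1.0:
        raise ValueError("signal_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal((n_timepoints, n_vertices))
    a = np.sqrt(signal_fraction)
    b = np.sqrt(1.0 - signal_fraction)
    data = [
        a * shared + b * rng.standard_normal((n_timepoints, n_vertices))
        for _ in range(n_participants)
    ]
    return ResponseCohort(data=data, signal_fraction=signal_fraction, seed=seed)
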