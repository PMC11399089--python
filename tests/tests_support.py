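"""Shared helpers for tests: handcrafted candidate sets."""

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from evensurf.mesh import edge_graph
from evensurf.sampling import CandidateSet, LossConfig


def toy_candidate_set_from_mesh(mesh, d_thr=100.0, eps=0.001):
    """CandidateSet whose candidates are the mesh vertices with graph geodesics."""
    dense = dijkstra(edge_graph(mesh), directed=False)
    np.fill_diagonal(dense, 0.0)
    return CandidateSet(
        sphere=mesh,
        distances=sp.csr_matrix(dense),
        config=LossConfig(d_thr=d_thr, eps=eps),
        template_ico=1,
        anatomy_per_subject=mesh.coordinates[None, :, :].copy(),
        anatomy_mean=mesh.coordinates.copy(),
    )
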