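"""Repulsion loss, coarse discrete optimization, and fine refinement."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from evensurf.mesh import TriangleMesh, edge_graph, make_icosphere
from evensurf.sampling import (
    _STEP_SIZES,
    _state_from_occupation,
    CandidateSet,
    FineOptimizer,
    LossConfig,
    build_candidate_set,
    calibrate_cutoff,
    coarse_initialize,
    coarse_optimize,
    default_cutoff,
    fine_optimize,
    pair_loss,
    relocate_vertex,
    total_loss,
)
from evensurf.synthetic import DistortionSpec, make_cohort


def _toy_candidate_set(points, dist_dense, d_thr, faces=None, eps=0.001):
    """Handcrafted CandidateSet from explicit points and a dense distance matrix."""
    n = len(points)
    if faces is None:
        faces = [[0, 1, 2]] + [[i, (i + 1) % n, (i + 2) % n] for i in range(n - 2)]
    mesh = TriangleMesh(np.asarray(points, dtype=float), np.asarray(faces))
    d = np.asarray(dist_dense, dtype=float).copy()
    np.fill_diagonal(d, 0.0)
    dist = sp.csr_matrix(d)
    return CandidateSet(
        sphere=mesh,
        distances=dist,
        config=LossConfig(d_thr=d_thr, eps=eps),
        template_ico=1,
        anatomy_per_subject=np.zeros((1, n, 3)),
        anatomy_mean=np.zeros((n, 3)),
    )


def _brute_force_loss(occ, candidates):
    cfg = candidates.config
    dense = candidates.distances.toarray()
    occ = list(occ)
    out = 0.0
    for a, b in itertools.combinations(range(len(occ)), 2):
        d = dense[occ[a], occ[b]]
        if 0 < d < cfg.d_thr:
            out += 1.0 / (d + cfg.eps) ** cfg.p
    return out


@pytest.fixture(scope="module")
def ico_candidates():
    """12 icosahedron vertices as candidates with graph geodesic distances."""
    mesh = make_icosphere(1, radius=10.0)
    dense = dijkstra(edge_graph(mesh), directed=False)
    return _toy_candidate_set(mesh.coordinates, dense, d_thr=100.0, faces=mesh.faces)


class TestPairLoss:
    def test_printed_values(self):
        cfg = LossConfig(p=4, d_thr=8.0, eps=0.0)
        assert pair_loss(1.0, cfg) == 1.0
        assert pair_loss(2.0, cfg) == 0.0625

    def test_cutoff_zeroes_far_pairs(self):
        cfg = LossConfig(p=4, d_thr=8.0)
        assert pair_loss(8.0, cfg) == 0.0
        assert pair_loss(100.0, cfg) == 0.0

    def test_zero_distance_without_regularizer_is_domain_error(self):
        with pytest.raises(ZeroDivisionError):
            pair_loss(0.0, LossConfig(d_thr=8.0), eps=0.0)

    def test_regularizer_keeps_zero_distance_finite(self):
        cfg = LossConfig(p=4, d_thr=8.0, eps=0.001)
        assert pair_loss(0.0, cfg) == pytest.approx(1e12)

    def test_cutoff_formula(self):
        assert default_cutoff(32) == 8.0
        assert default_cutoff(64) == 4.0


class TestTotalLoss:
    def test_single_pair_at_unit_distance(self):
        pts = np.eye(4, 3) + 0.1
        dense = np.full((4, 4), 5.0)
        dense[0, 1] = dense[1, 0] = 1.0
        cs = _toy_candidate_set(pts, dense, d_thr=3.0, eps=0.0)
        st = _state_from_occupation(cs, np.array([0, 1]))
        assert total_loss(st, cs) == pytest.approx(1.0)

    def test_pair_beyond_cutoff_contributes_nothing(self):
        pts = np.eye(4, 3) + 0.1
        dense = np.full((4, 4), 5.0)
        cs = _toy_candidate_set(pts, dense, d_thr=3.0)
        st = _state_from_occupation(cs, np.array([0, 2]))
        assert total_loss(st, cs) == 0.0
        assert st.loss == 0.0

    def test_matches_brute_force_double_loop(self, tiny_candidates, rng):
        occ = rng.choice(tiny_candidates.n_candidates, size=10, replace=False)
        st = _state_from_occupation(tiny_candidates, occ)
        assert total_loss(st, tiny_candidates) == pytest.approx(
            _brute_force_loss(occ, tiny_candidates), rel=1e-10
        )


class TestCandidateSet:
    def test_counts_and_ratio(self, small_cohort):
        cs = build_candidate_set(small_cohort, template_ico=2, candidate_ico=8)
        assert cs.n_candidates == 10 * 8**2 + 2
        assert cs.template_n == 10 * 2**2 + 2
        ratio = cs.n_candidates / cs.template_n
        assert round(ratio / 8) * 8 == 16  # 4x linear oversampling => 16x count

    def test_distances_symmetric_and_cut(self, tiny_candidates):
        d = tiny_candidates.distances
        assert (d - d.T).nnz == 0
        assert d.data.max() <= tiny_candidates.config.d_thr
        assert d.data.min() > 0

    def test_sphere_cohort_distances_near_euclidean(self):
        spec = DistortionSpec(ico_order=8, alpha=0.0, jitter=0.0, seed=0)
        cohort = make_cohort(spec, 1)
        cs = build_candidate_set(cohort, 2, 8, config=LossConfig(d_thr=20.0))
        row = cs.distances.getrow(0)
        chord = np.linalg.norm(
            cs.sphere.coordinates[row.indices] - cs.sphere.coordinates[0], axis=1
        )
        # graph geodesic is at least the chord and within lattice slack of it
        assert np.all(row.data >= chord - 1e-9)
        assert np.all(row.data <= 1.3 * chord + 1e-9)

    def test_candidate_ratio_guard(self, small_cohort):
        with pytest.raises(ValueError):
            build_candidate_set(small_cohort, template_ico=8, candidate_ico=8)

    def test_calibrated_cutoff_scales_with_anatomy(self, small_cohort):
        """The calibrated cutoff is twice the mean anatomical edge length."""
        d_thr = calibrate_cutoff(small_cohort, 2)
        sphere_spacing = 2.0 * np.mean(
            np.linalg.norm(
                np.diff(make_icosphere(2, radius=100.0).coordinates[
                    make_icosphere(2).edges()], axis=1).squeeze(), axis=-1)
        )
        # the distorted anatomy is larger than the sphere, so the cutoff grows
        assert d_thr > 0.8 * sphere_spacing

    def test_distance_modes_agree_for_identical_subjects(self, small_cohort):
        from evensurf.io import Cohort, SubjectSurface

        s = small_cohort.subjects[0]
        twins = Cohort([s, SubjectSurface("twin", s.sphere, s.anatomy)])
        cfg = LossConfig(d_thr=40.0)
        a = build_candidate_set(twins, 2, 8, config=cfg, distance_mode="mean-edge")
        b = build_candidate_set(twins, 2, 8, config=cfg, distance_mode="mean-dijkstra")
        assert np.allclose((a.distances - b.distances).data, 0.0, atol=1e-9)


class TestCoarseOptimization:
    def test_initialize_deterministic_and_distinct(self, tiny_candidates):
        a = coarse_initialize(tiny_candidates, n=20, seed=3)
        b = coarse_initialize(tiny_candidates, n=20, seed=3)
        assert np.array_equal(a.candidate_indices, b.candidate_indices)
        assert len(set(a.candidate_indices)) == 20

    def test_initial_candidate_losses_match_brute_force(self, tiny_candidates):
        st = coarse_initialize(tiny_candidates, n=15, seed=0)
        dense = tiny_candidates.distances.toarray()
        cfg = tiny_candidates.config
        occ = set(st.candidate_indices)
        for c in list(occ)[:5] + [0, 1, 2]:
            expected = sum(
                1.0 / (dense[c, o] + cfg.eps) ** cfg.p
                for o in occ
                if o != c and 0 < dense[c, o] < cfg.d_thr
            )
            assert st.cand_loss[c] == pytest.approx(expected, rel=1e-10)

    def test_relocation_is_fixed_point_at_global_minimum(self, ico_candidates):
        # antipodal pair on the icosahedron is already optimal
        st = _state_from_occupation(ico_candidates, np.array([0, 3]))
        d03 = ico_candidates.distances[0, 3]
        assert d03 == ico_candidates.distances.data.max()  # truly antipodal
        moved = relocate_vertex(st, ico_candidates, 0)
        assert not moved

    def test_ring_converges_to_antipodal_pair(self):
        """2 vertices on 4 ring candidates end up opposite each other."""
        theta = np.linspace(0, 2 * np.pi, 4, endpoint=False)
        pts = np.c_[np.cos(theta), np.sin(theta), np.full(4, 0.5)]
        adjacent, opposite = 1.0, 2.0
        dense = np.full((4, 4), adjacent)
        dense[0, 2] = dense[2, 0] = dense[1, 3] = dense[3, 1] = opposite
        cs = _toy_candidate_set(pts, dense, d_thr=10.0)
        best_bf = min(
            _brute_force_loss(c, cs) for c in itertools.combinations(range(4), 2)
        )
        st = coarse_optimize(cs, n=2, max_sweeps=10, restarts=6, seed=0)
        assert st.loss == pytest.approx(best_bf, rel=1e-12)
        i, j = sorted(st.candidate_indices)
        assert (j - i) == 2  # antipodal

    def test_incremental_loss_equals_recomputation(self, tiny_candidates, rng):
        st = coarse_initialize(tiny_candidates, n=25, seed=1)
        for k in rng.permutation(25):
            relocate_vertex(st, tiny_candidates, int(k))
            assert st.loss == pytest.approx(
                _brute_force_loss(st.candidate_indices, tiny_candidates), rel=1e-8, abs=1e-15
            )

    def test_relocation_never_increases_loss(self, tiny_candidates, rng):
        st = coarse_initialize(tiny_candidates, n=25, seed=2)
        prev = st.loss
        for k in rng.permutation(25):
            relocate_vertex(st, tiny_candidates, int(k))
            assert st.loss <= prev + 1e-12
            prev = st.loss

    def test_zero_sweeps_returns_initialization(self, tiny_candidates):
        st0 = coarse_initialize(tiny_candidates, n=20, seed=5)
        st = coarse_optimize(tiny_candidates, n=20, max_sweeps=0, restarts=1, seed=5)
        assert np.array_equal(np.sort(st.candidate_indices), np.sort(st0.candidate_indices))

    def test_attains_exhaustive_optimum_on_tiny_instance(self, ico_candidates):
        """With enough restarts the greedy search finds the global optimum."""
        best_bf = min(
            _brute_force_loss(c, ico_candidates)
            for c in itertools.combinations(range(12), 4)
        )
        st = coarse_optimize(ico_candidates, n=4, max_sweeps=20, restarts=25, seed=0)
        assert st.loss == pytest.approx(best_bf, rel=1e-10)

    def test_too_many_vertices_rejected(self, ico_candidates):
        with pytest.raises(ValueError):
            coarse_initialize(ico_candidates, n=13)


@pytest.fixture(scope="module")
def sphere_pair():
    """Two template vertices ~25 mm apart on an undistorted sphere cohort."""
    spec = DistortionSpec(ico_order=8, alpha=0.0, jitter=0.0, seed=0)
    cohort = make_cohort(spec, 1)
    cs = build_candidate_set(cohort, 2, 8, config=LossConfig(d_thr=60.0))
    c = cs.sphere.coordinates
    i = 100
    d = np.linalg.norm(c - c[i], axis=1)
    j = int(np.argmin(np.abs(d - 25)))
    return cs, i, j


class TestFineOptimization:
    def test_two_vertex_gradient_points_toward_neighbor(self, sphere_pair):
        """Descent direction matches the analytic repulsion direction.

        The estimate interpolates graph geodesics, whose lattice anisotropy
        tilts the direction by about a degree on this mesh.
        """
        cs, i, j = sphere_pair
        st = _state_from_occupation(cs, np.array([i, j]))
        opt = FineOptimizer(cs, st)
        g = opt.gradient(0)
        desc = -g / np.linalg.norm(g)
        c = cs.sphere.coordinates
        away = c[i] - c[j]
        nrm = c[i] / np.linalg.norm(c[i])
        away_t = away - (away @ nrm) * nrm
        away_t /= np.linalg.norm(away_t)
        angle = np.arccos(np.clip(desc @ away_t, -1, 1))
        assert angle < 0.035  # rad

    def test_symmetric_equilibrium_has_zero_gradient(self, sphere_pair):
        cs, _, _ = sphere_pair
        # the 12 icosahedron vertices (first 12 candidates) are symmetric
        st = _state_from_occupation(cs, np.arange(12))
        opt = FineOptimizer(cs, st)
        for k in range(12):
            assert np.linalg.norm(opt.gradient(k)) < 1e-12

    def test_isolated_vertex_has_zero_gradient_and_step(self, sphere_pair):
        cs, i, _ = sphere_pair
        antipode = int(np.argmin(cs.sphere.coordinates @ cs.sphere.coordinates[i]))
        st = _state_from_occupation(cs, np.array([i, antipode]))
        opt = FineOptimizer(cs, st)
        assert np.linalg.norm(opt.gradient(0)) == 0.0
        assert np.allclose(opt.propose(0), 0.0)

    def test_line_search_has_thirteen_steps_including_null(self):
        assert len(_STEP_SIZES) == 13
        assert _STEP_SIZES[0] == 0.0
        assert _STEP_SIZES[1] == 2.0**-21
        assert _STEP_SIZES[-1] == 2.0**-10

    def test_applied_step_is_half_the_line_search_argmin(self, sphere_pair):
        cs, i, j = sphere_pair
        st = _state_from_occupation(cs, np.array([i, j]))
        opt = FineOptimizer(cs, st)
        g = opt.gradient(0)
        direction = -g / np.linalg.norm(g)
        q = opt.positions[0]
        losses = [opt.vertex_loss(0, int(opt.faces[0]), opt.weights[0])]
        for s in _STEP_SIZES[1:]:
            p = q + s * opt.unit * direction
            losses.append(opt._loss_at(0, p * (opt.radius / np.linalg.norm(p))))
        best = int(np.argmin(losses))
        expected = 0.5 * _STEP_SIZES[best] * opt.unit * direction
        assert np.allclose(opt.propose(0), expected)
        assert best > 0  # a genuine move for this pair

    def test_zero_rounds_is_identity(self, tiny_candidates):
        st = coarse_optimize(tiny_candidates, n=30, max_sweeps=5, restarts=1, seed=0)
        stf = fine_optimize(st, tiny_candidates, n_rounds=0)
        assert np.allclose(stf.positions, st.positions)

    def test_fine_never_increases_loss(self, tiny_candidates):
        for seed in range(3):
            st = coarse_optimize(tiny_candidates, n=30, max_sweeps=5, restarts=1, seed=seed)
            stf = fine_optimize(st, tiny_candidates, n_rounds=3)
            assert stf.loss <= st.loss + 1e-12 * max(1.0, st.loss)

    def test_round_reduces_loss_off_equilibrium(self, sphere_pair):
        cs, i, j = sphere_pair
        st = _state_from_occupation(cs, np.array([i, j]))
        opt = FineOptimizer(cs, st)
        old, new = opt.run_round()
        assert new < old

    def test_fine_state_loss_matches_recomputation(self, tiny_candidates):
        st = coarse_optimize(tiny_candidates, n=30, max_sweeps=5, restarts=1, seed=1)
        stf = fine_optimize(st, tiny_candidates, n_rounds=2)
        assert stf.loss == pytest.approx(total_loss(stf, tiny_candidates), rel=1e-8)
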