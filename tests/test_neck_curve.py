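"""Snapping, A* shortest paths, curve building, local subdivision."""

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as sp_dijkstra
from scipy.spatial.distance import cdist

import aneusep as an
from aneusep.errors import (DegeneratePickError, NoPathError, ValidationError)
from aneusep.neck_curve import (EdgeGraph, path_length, shortest_path,
                                snap_points)

from conftest import make_icosahedron


def sparse_graph(mesh):
    edges, w = mesh.edges_unique()
    n = mesh.n_vertices
    return coo_matrix(
        (np.r_[w, w], (np.r_[edges[:, 0], edges[:, 1]],
                       np.r_[edges[:, 1], edges[:, 0]])), shape=(n, n)).tocsr()


class TestSnapPoints:
    def test_exact_hit_returns_that_vertex(self, tetra):
        picks = an.PickedPointSet(tetra.vertices[[1, 2, 3]])
        assert list(snap_points(tetra, picks)) == [1, 2, 3]

    def test_tie_broken_by_lowest_index(self):
        # two vertices symmetric about the pick
        verts = np.array([[0, 0, 0], [2, 0, 0], [1, 1, 0], [1, -1, 0]], float)
        faces = np.array([[0, 1, 2], [1, 0, 3]])
        mesh = an.TriangleMesh(verts, faces)
        picks = an.PickedPointSet([[1.0, 0.0, 0.0],    # equidistant to all 4 vertices
                                   [1.0, 1.0, 0.0], [0.9, -0.9, 0.0]])
        snapped = snap_points(mesh, picks)
        assert snapped[0] == 0  # four-way tie -> lowest index wins

    def test_matches_brute_force_scan(self, lateral_phantom):
        _, mesh, _ = lateral_phantom
        rng = np.random.default_rng(3)
        pts = rng.uniform(mesh.vertices.min(0), mesh.vertices.max(0), (10, 3))
        snapped = snap_points(mesh, an.PickedPointSet(pts))
        kept = []
        for p in pts:
            d = np.linalg.norm(mesh.vertices - p, axis=1)
            kept.append(int(np.argmin(d)))  # argmin takes lowest index on ties
        expect = [v for i, v in enumerate(kept) if i == 0 or v != kept[i - 1]]
        if expect[0] == expect[-1]:
            expect.pop()
        assert list(snapped) == expect

    def test_degenerate_picks_rejected(self, tetra):
        picks = an.PickedPointSet(np.array([tetra.vertices[0]] * 4) + 1e-9)
        with pytest.raises(DegeneratePickError):
            snap_points(tetra, picks)


class TestShortestPath:
    def test_identity_path(self, lateral_graph):
        assert shortest_path(lateral_graph, 5, 5) == [5]

    def test_adjacent_icosahedron_vertices_share_one_edge(self):
        ico = make_icosahedron()
        g = EdgeGraph.from_mesh(ico)
        a, b = (int(x) for x in ico.faces[0][:2])
        assert shortest_path(g, a, b) == sorted([a, b]) or \
            shortest_path(g, a, b) == [a, b]
        assert len(shortest_path(g, a, b)) == 2

    @pytest.mark.parametrize("preset", ["lateral", "bifurcation", "sidebranch"])
    def test_astar_cost_equals_dijkstra(self, preset):
        spec = {"lateral": an.lateral_preset, "bifurcation": an.bifurcation_preset,
                "sidebranch": an.sidebranch_preset}[preset](voxel=0.4, seed=9)
        mesh, _ = an.phantom_mesh(spec)
        g = EdgeGraph.from_mesh(mesh)
        A = sparse_graph(mesh)
        rng = np.random.default_rng(17)
        pairs = rng.integers(0, mesh.n_vertices, size=(60, 2))
        for a, b in pairs:
            p = shortest_path(g, int(a), int(b))
            d = sp_dijkstra(A, indices=[int(a)])[0, int(b)]
            assert abs(path_length(g, p) - d) < 1e-9

    def test_disconnected_components_raise(self, tetra):
        # two disjoint tetrahedra in one mesh
        verts = np.vstack([tetra.vertices, tetra.vertices + 10.0])
        faces = np.vstack([tetra.faces, tetra.faces + 4])
        mesh = an.TriangleMesh(verts, faces)
        g = EdgeGraph.from_mesh(mesh)
        with pytest.raises(NoPathError):
            shortest_path(g, 0, 5)

    def test_deterministic(self, lateral_graph):
        p1 = shortest_path(lateral_graph, 10, 500)
        p2 = shortest_path(lateral_graph, 10, 500)
        assert p1 == p2


class TestBuildNeckCurve:
    def test_three_adjacent_picks_give_triangle_loop(self, tetra):
        picks = an.PickedPointSet(tetra.vertices[[0, 1, 2]])
        curve = an.build_neck_curve(tetra, picks)
        assert len(curve) == 3
        assert set(curve.vertex_indices) == {0, 1, 2}

    def test_two_distinct_picks_degenerate(self, tetra):
        pts = np.vstack([tetra.vertices[0], tetra.vertices[1], tetra.vertices[0]])
        with pytest.raises(DegeneratePickError):
            an.build_neck_curve(tetra, an.PickedPointSet(pts))

    def test_curve_tracks_analytic_neck(self, lateral_phantom, gt_neck_curve):
        spec, _, gt = lateral_phantom
        d = cdist(gt_neck_curve.points, gt).min(axis=1)
        assert d.mean() <= 2 * spec.voxel

    def test_invariant_under_cyclic_pick_rotation(self, lateral_phantom,
                                                  lateral_graph):
        spec, mesh, gt = lateral_phantom
        pts = gt[:: len(gt) // 7][:7]
        loops = []
        for shift in (0, 3, 5):
            picks = an.PickedPointSet(np.roll(pts, shift, axis=0))
            c = an.build_neck_curve(mesh, picks, graph=lateral_graph)
            loops.append(c)
        def canon(curve):
            idx = list(curve.vertex_indices)
            k = idx.index(min(idx))
            fwd = tuple(idx[k:] + idx[:k])
            rev = tuple([fwd[0]] + list(fwd[1:])[::-1])
            return min(fwd, rev)
        assert canon(loops[0]) == canon(loops[1]) == canon(loops[2])

    def test_result_validates_on_mesh(self, gt_neck_curve, lateral_phantom):
        _, mesh, _ = lateral_phantom
        gt_neck_curve.validate_on(mesh)  # consecutive steps are edges, no repeats


class TestSubdivideRegion:
    def test_area_conserved_and_vertices_preserved(self, lateral_phantom,
                                                   gt_neck_curve):
        _, mesh, _ = lateral_phantom
        m2, c2 = an.subdivide_region(mesh, gt_neck_curve, radius=1.2)
        assert abs(m2.area() - mesh.area()) <= 1e-9 * mesh.area()
        np.testing.assert_array_equal(m2.vertices[:mesh.n_vertices], mesh.vertices)
        c2.validate_on(m2)

    def test_new_vertices_are_original_edge_midpoints(self, lateral_phantom,
                                                      gt_neck_curve):
        # Hausdorff distance 0: every new vertex lies at an old edge midpoint
        _, mesh, _ = lateral_phantom
        m2, _ = an.subdivide_region(mesh, gt_neck_curve, radius=0.9)
        new = m2.vertices[mesh.n_vertices:]
        edges, _ = mesh.edges_unique()
        mids = 0.5 * (mesh.vertices[edges[:, 0]] + mesh.vertices[edges[:, 1]])
        d = cdist(new, mids).min(axis=1)
        assert d.max() == 0.0

    def test_refinement_stays_local(self, lateral_phantom, gt_neck_curve):
        _, mesh, _ = lateral_phantom
        radius = 0.7
        m2, _ = an.subdivide_region(mesh, gt_neck_curve, radius=radius)
        new = m2.vertices[mesh.n_vertices:]
        _, lengths = mesh.edges_unique()
        d = cdist(new, gt_neck_curve.points).min(axis=1)
        assert d.max() <= radius + 2.5 * lengths.max()

    def test_rebuilt_curve_error_nonincreasing_with_radius(self, lateral_phantom):
        spec, mesh, gt = lateral_phantom
        rng = np.random.default_rng(11)
        from aneusep.phantom import _arc_positions, _tangential_noise
        pts = _arc_positions(gt, np.sort(rng.uniform(0, 1, 8)))
        pts = _tangential_noise(spec, pts, spec.voxel, rng)
        picks = an.PickedPointSet(pts)
        base = an.build_neck_curve(mesh, picks)
        def err(curve):
            return cdist(curve.points, gt).min(axis=1).mean()
        errors = [err(base)]
        for mult in (2, 4, 8):
            m2, _ = an.subdivide_region(mesh, base, radius=mult * spec.voxel)
            errors.append(err(an.build_neck_curve(m2, picks)))
        assert all(b <= a + 1e-9 for a, b in zip(errors, errors[1:]))

    def test_invalid_radius(self, lateral_phantom, gt_neck_curve):
        _, mesh, _ = lateral_phantom
        with pytest.raises(ValidationError):
            an.subdivide_region(mesh, gt_neck_curve, radius=0.0)
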