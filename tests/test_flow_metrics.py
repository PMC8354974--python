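"""Hemodynamic summaries: OSI, AWSS, neck inflow and the solution table."""

import numpy as np
import pytest

import aneusep as an
from aneusep.core_mesh import SurfaceFieldSeries
from aneusep.errors import ValidationError
from aneusep.ostium import OstiumPatch
from aneusep.phantom import FieldParams, paraboloid_inflow, synthetic_fields


def const_series(vec, n_el=4, n_t=17):
    t = np.linspace(0.0, 1.0, n_t)
    v = np.tile(np.asarray(vec, float), (n_t, n_el, 1))
    return SurfaceFieldSeries(np.arange(n_el), t, v)


def flat_patch(area=10.0):
    """Flat square patch of the given area in the z=0 plane (normals +z)."""
    s = np.sqrt(area)
    verts = np.array([[0, 0, 0], [s, 0, 0], [s, s, 0], [0, s, 0]], float)
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return OstiumPatch(verts, faces, n_boundary=4)


class TestOsi:
    def test_constant_field_zero(self):
        osi = an.osi_per_element(const_series([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(osi, 0.0, atol=1e-12)

    def test_zero_mean_sinusoid_half(self):
        t = np.linspace(0, 1, 129)
        v = np.sin(2 * np.pi * t)[:, None, None] * np.array([0.0, 1.0, 0.0])
        osi = an.osi_per_element(SurfaceFieldSeries([0], t, v))
        assert abs(osi[0] - 0.5) < 1e-3

    def test_two_direction_half_cycle_closed_form(self):
        n = 2049
        t = np.linspace(0, 1, n)
        v = np.zeros((n, 1, 3))
        v[t < 0.5, 0, 0] = 1.0
        v[t > 0.5, 0, 1] = 1.0
        v[np.isclose(t, 0.5), 0, :2] = 0.5
        osi = an.osi_per_element(SurfaceFieldSeries([0], t, v))[0]
        assert abs(osi - 0.5 * (1 - np.sqrt(2) / 2)) < 1e-3

    def test_zero_field_defined_as_zero(self):
        osi = an.osi_per_element(const_series([0.0, 0.0, 0.0]))
        np.testing.assert_array_equal(osi, 0.0)

    def test_bounds_on_random_fields(self):
        rng = np.random.default_rng(6)
        t = np.linspace(0, 1, 33)
        v = rng.normal(size=(33, 50, 3))
        osi = an.osi_per_element(SurfaceFieldSeries(np.arange(50), t, v))
        assert (osi >= 0).all() and (osi <= 0.5).all()

    def test_single_time_sample_rejected(self):
        with pytest.raises(ValidationError):
            SurfaceFieldSeries([0], np.array([0.0]), np.zeros((1, 1, 3)))


@pytest.fixture(scope="module")
def sac(lateral_phantom, gt_neck_curve):
    spec, mesh, _ = lateral_phantom
    return an.extract_sac(mesh, gt_neck_curve, dome_seed=spec.dome_apex)


class TestAwss:
    def test_constant_magnitude_recovered(self, lateral_phantom, sac):
        _, mesh, _ = lateral_phantom
        series = const_series([0.0, 0.0, 3.5], n_el=mesh.n_faces)
        assert an.awss(series, sac) == pytest.approx(3.5, rel=1e-12)

    def test_linearity_in_magnitude(self, lateral_phantom, sac):
        _, mesh, _ = lateral_phantom
        rng = np.random.default_rng(1)
        t = np.linspace(0, 1, 17)
        v = rng.normal(size=(17, mesh.n_faces, 3))
        s1 = SurfaceFieldSeries(np.arange(mesh.n_faces), t, v)
        s2 = SurfaceFieldSeries(np.arange(mesh.n_faces), t, 2.0 * v)
        assert an.awss(s2, sac) == pytest.approx(2 * an.awss(s1, sac), rel=1e-12)

    def test_matches_refined_quadrature_oracle(self, lateral_phantom, sac):
        # smooth band-limited series: trapezoid at 256 samples vs 4096
        _, mesh, _ = lateral_phantom
        rng = np.random.default_rng(9)
        amp = rng.normal(size=(3, mesh.n_faces, 3))
        def series(n):
            t = np.linspace(0, 1, n)
            v = sum(amp[k][None] * np.sin(2 * np.pi * (k + 1) * t + k)[:, None, None]
                    for k in range(3)) + 2.0
            return SurfaceFieldSeries(np.arange(mesh.n_faces), t, v)
        assert an.awss(series(256), sac) == pytest.approx(
            an.awss(series(4096), sac), abs=1e-6)


class TestQIn:
    def test_uniform_normal_flow_closed_form(self):
        patch = flat_patch(area=10.0)
        series = const_series([0.0, 0.0, 100.0], n_el=2)  # mm/s along +z
        qi, qn = an.q_in(series, patch)
        assert qi == pytest.approx(1.0, rel=1e-12)   # 1000 mm^3/s = 1 mL/s
        assert qn == pytest.approx(1.0, rel=1e-12)

    def test_reversed_orientation_gives_zero_inflow(self):
        patch = flat_patch(area=10.0)
        flipped = OstiumPatch(patch.vertices, patch.faces[:, ::-1].copy(), 4)
        series = const_series([0.0, 0.0, 100.0], n_el=2)
        qi, qn = an.q_in(series, flipped)
        assert qi == 0.0
        assert qn == pytest.approx(-1.0, rel=1e-12)

    def test_half_in_half_out(self):
        patch = flat_patch(area=10.0)
        t = np.linspace(0, 1, 9)
        v = np.zeros((9, 2, 3))
        v[:, 0, 2] = 100.0    # one triangle inflow
        v[:, 1, 2] = -100.0   # the other outflow
        qi, qn = an.q_in(SurfaceFieldSeries(np.arange(2), t, v), patch)
        assert qi == pytest.approx(0.5, rel=1e-12)   # v*A/2
        assert qn == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance_and_velocity_scaling(self):
        patch = flat_patch(area=10.0)
        th = 0.6
        R = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0],
                      [-np.sin(th), 0, np.cos(th)]])
        moved = OstiumPatch(patch.vertices @ R.T + [5, 6, 7], patch.faces, 4)
        t = np.linspace(0, 1, 9)
        vec = np.array([0.0, 0.0, 100.0]) @ R.T
        v = np.tile(vec, (9, 2, 1))
        qi, _ = an.q_in(SurfaceFieldSeries(np.arange(2), t, v), moved)
        assert qi == pytest.approx(1.0, rel=1e-9)
        qi2, _ = an.q_in(SurfaceFieldSeries(np.arange(2), t, 3 * v), moved)
        assert qi2 == pytest.approx(3.0, rel=1e-9)


class TestMetricsForSolutions:
    def test_identical_curves_all_zero_percent(self, lateral_phantom,
                                               lateral_curves):
        spec, mesh, _ = lateral_phantom
        curve = lateral_curves[0]
        curves = {s: curve for s in ("min", "median", "max")}
        t = np.linspace(0, 1, 9)
        wss = const_series([1.0, 0.5, 0.0], n_el=mesh.n_faces, n_t=9)
        rows, table = an.metrics_for_solutions(
            mesh, curves, wss,
            lambda patch, lab: paraboloid_inflow(patch, 1.0, t),
            dome_seed=spec.dome_apex)
        for col in ("A_a", "Q_in", "AWSS_bar", "OSI_bar", "OSI_max"):
            assert (table[f"{col}_rel_pct"] == 0.0).all()

    def test_report_column_order(self, lateral_phantom, lateral_curves):
        spec, mesh, _ = lateral_phantom
        curves = {s: lateral_curves[i] for s, i in
                  zip(("min", "median", "max"), (0, 1, 2))}
        t = np.linspace(0, 1, 9)
        wss = const_series([1.0, 0.0, 0.0], n_el=mesh.n_faces, n_t=9)
        _, table = an.metrics_for_solutions(
            mesh, curves, wss,
            lambda patch, lab: paraboloid_inflow(patch, 1.0, t),
            dome_seed=spec.dome_apex)
        assert list(table.columns[:5]) == ["A_a", "Q_in", "AWSS_bar",
                                           "OSI_bar", "OSI_max"]
        assert list(table.index) == ["min", "median", "max"]

    def test_neck_band_bump_raises_awss_of_larger_sac(self, lateral_phantom,
                                                      lateral_graph):
        # two nested sacs: the wider one includes the high-shear neck band,
        # so its mean AWSS must strictly exceed the tighter one's
        spec, mesh, gt = lateral_phantom
        picks_neck = an.PickedPointSet(gt[:: len(gt) // 8][:8])
        wide = an.build_neck_curve(mesh, picks_neck, graph=lateral_graph)
        from aneusep.phantom import _slide_toward_dome
        tight_pts = _slide_toward_dome(spec, picks_neck.points, 2.0)
        tight = an.build_neck_curve(mesh, an.PickedPointSet(tight_pts),
                                    graph=lateral_graph)
        patch = an.smooth_patch(an.triangulate_cap(wide))
        wss, _ = synthetic_fields(mesh, gt, patch,
                                  FieldParams(neck_amp=10.0, neck_sigma=0.8),
                                  spec=spec, seed=0)
        sac_wide = an.extract_sac(mesh, wide, dome_seed=spec.dome_apex)
        sac_tight = an.extract_sac(mesh, tight, dome_seed=spec.dome_apex)
        assert len(sac_wide.face_ids) > len(sac_tight.face_ids)
        assert an.awss(wss, sac_wide) > an.awss(wss, sac_tight)
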