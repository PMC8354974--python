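"""Pairwise curve distances, median curve, group splits, reports."""

import numpy as np
import pytest

import aneusep as an
from aneusep.errors import ValidationError
from aneusep.variability import (CurveDistanceMatrix, batch_export,
                                 read_heatmap_csv)


def brute_directed(pa, pb):
    total = 0.0
    for p in pa:
        total += min(np.linalg.norm(p - q) for q in pb) ** 2
    return np.sqrt(total)


def random_curve(rng, n):
    return rng.normal(size=(n, 3)) * 3.0


class TestDirectedDistance:
    def test_identical_curves_zero(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0.0]])
        assert an.directed_distance(pts, pts) == 0.0

    def test_hand_example_asymmetric(self):
        a = np.array([[0, 0, 0], [1, 0, 0.0]])
        b = np.array([[0, 0, 0.0]])
        assert an.directed_distance(a, b) == pytest.approx(1.0)
        assert an.directed_distance(b, a) == pytest.approx(0.0)
        assert an.pairwise_distance(a, b) == pytest.approx(0.5)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            pa = random_curve(rng, rng.integers(3, 40))
            pb = random_curve(rng, rng.integers(3, 40))
            assert an.directed_distance(pa, pb) == pytest.approx(
                brute_directed(pa, pb), abs=1e-9)
            assert an.pairwise_distance(pa, pb) == pytest.approx(
                0.5 * (brute_directed(pa, pb) + brute_directed(pb, pa)),
                abs=1e-9)

    def test_symmetric_premetric(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            pa, pb = random_curve(rng, 15), random_curve(rng, 22)
            assert an.pairwise_distance(pa, pb) == pytest.approx(
                an.pairwise_distance(pb, pa), abs=1e-12)
            assert an.pairwise_distance(pa, pb) >= 0
            assert an.pairwise_distance(pa, pa) == 0.0

    def test_empty_curve_rejected(self):
        with pytest.raises(ValidationError):
            an.directed_distance(np.empty((0, 3)), np.zeros((3, 3)))


class TestDistanceMatrix:
    def test_single_curve_zero_matrix(self, lateral_curves):
        one = an.CurveSet(curves=[lateral_curves[0]],
                          case_id=lateral_curves.case_id)
        m = an.distance_matrix(one)
        assert m.values.shape == (1, 1) and m.values[0, 0] == 0.0
        assert an.median_curve(m) == 0

    def test_matches_entrywise_brute_force(self, lateral_curves):
        subset = an.CurveSet(curves=list(lateral_curves)[:3],
                             case_id=lateral_curves.case_id)
        m = an.distance_matrix(subset)
        for i in range(3):
            for j in range(3):
                expect = 0.0 if i == j else 0.5 * (
                    brute_directed(subset[i].points, subset[j].points)
                    + brute_directed(subset[j].points, subset[i].points))
                assert m.values[i, j] == pytest.approx(expect, abs=1e-9)

    def test_permutation_equivariance(self, lateral_curves):
        m = an.distance_matrix(lateral_curves)
        perm = np.random.default_rng(0).permutation(len(lateral_curves))
        shuffled = an.CurveSet(curves=[lateral_curves[i] for i in perm],
                               case_id=lateral_curves.case_id)
        m2 = an.distance_matrix(shuffled)
        np.testing.assert_allclose(m2.values, m.values[np.ix_(perm, perm)],
                                   atol=1e-12)

    def test_invariants(self, lateral_curves):
        m = an.distance_matrix(lateral_curves)
        assert (m.values >= 0).all()
        np.testing.assert_allclose(m.values, m.values.T)
        np.testing.assert_allclose(np.diag(m.values), 0.0)


class TestMedianCurve:
    def test_argmin_equals_exhaustive_scan(self, lateral_curves):
        m = an.distance_matrix(lateral_curves)
        best = min(range(len(m)), key=lambda i: (m.values[i].sum(), i))
        assert an.median_curve(m) == best

    def test_tie_broken_by_lowest_index(self):
        vals = np.array([[0.0, 1.0], [1.0, 0.0]])
        m = CurveDistanceMatrix(vals, ("b", "a"))
        assert an.median_curve(m) == 0

    def test_outlier_never_median(self, lateral_phantom, lateral_graph):
        spec, mesh, gt = lateral_phantom
        for seed in range(10):
            curves = an.simulated_annotators(mesh, spec, gt, n_users=6,
                                             graph=lateral_graph, seed=seed)
            m = an.distance_matrix(curves)
            med = an.median_curve(m)
            # the outlier is the last user and has the largest row sum
            assert np.argmax(m.row_sums()) == len(curves) - 1
            assert med != len(curves) - 1


class TestGroupSplit:
    def test_all_same_group_identical(self, lateral_curves):
        m = an.distance_matrix(lateral_curves)
        uniform = CurveDistanceMatrix(m.values, m.annotator_ids,
                                      ("clinical",) * len(m))
        sub, med = an.group_split(uniform, "clinical")
        np.testing.assert_array_equal(sub.values, m.values)
        assert med == an.median_curve(m)

    def test_submatrix_is_principal_submatrix(self, lateral_curves):
        m = an.distance_matrix(lateral_curves)
        sel = [i for i, g in enumerate(m.groups) if g == "clinical"]
        sub, _ = an.group_split(m, "clinical")
        np.testing.assert_array_equal(sub.values, m.values[np.ix_(sel, sel)])
        assert list(sub.annotator_ids) == [m.annotator_ids[i] for i in sel]

    def test_group_medians_can_differ_from_global(self):
        # constructed: annotator 0 is global median, but within group B the
        # median is annotator 2
        vals = np.array([
            [0.0, 1.0, 1.0, 1.0],
            [1.0, 0.0, 5.0, 5.0],
            [1.0, 5.0, 0.0, 0.5],
            [1.0, 5.0, 0.5, 0.0]])
        m = CurveDistanceMatrix(vals, ("w", "x", "y", "z"),
                                ("clinical", "clinical",
                                 "nonclinical", "nonclinical"))
        assert an.median_curve(m) == 0
        sub, med = an.group_split(m, "nonclinical")
        assert sub.annotator_ids[med] in ("y", "z")

    def test_unknown_group_rejected(self, lateral_curves):
        m = an.distance_matrix(lateral_curves)
        with pytest.raises(ValidationError):
            an.group_split(m, "astronauts")


class TestRelativeReport:
    @pytest.mark.parametrize("values,expect_min,expect_max", [
        ({"min": 4.020, "median": 4.632, "max": 4.803}, -13.2, 3.7),
        ({"min": 1.034, "median": 1.543, "max": 1.887}, -33.0, 22.3),
        ({"min": 2.0, "median": 2.0, "max": 2.0}, 0.0, 0.0),
    ])
    def test_percent_differences(self, values, expect_min, expect_max):
        rel = an.relative_report(values)
        assert rel["min"] == pytest.approx(expect_min, abs=1e-12)
        assert rel["max"] == pytest.approx(expect_max, abs=1e-12)

    def test_rounding_half_away_from_zero(self):
        rel = an.relative_report({"min": 100.25, "median": 100.0, "max": 99.75})
        assert rel["min"] == 0.3 and rel["max"] == -0.3

    def test_missing_entry_rejected(self):
        with pytest.raises(ValidationError):
            an.relative_report({"min": 1.0, "max": 2.0})


class TestHeatmapExport:
    def test_single_cell(self, tmp_path):
        m = CurveDistanceMatrix(np.zeros((1, 1)), ("only",))
        p = an.export_heatmap(m, tmp_path / "h.csv")
        back = read_heatmap_csv(p)
        assert back.values[0, 0] == 0.0

    def test_csv_roundtrip_and_median_flag(self, tmp_path, lateral_curves):
        m = an.distance_matrix(lateral_curves)
        p = an.export_heatmap(m, tmp_path / "h.csv")
        text = p.read_text()
        med_id = m.annotator_ids[an.median_curve(m)]
        assert f"{med_id}*" in text
        back = read_heatmap_csv(p)
        np.testing.assert_array_equal(back.values, m.values)

    def test_batch_shared_scale_sidecar(self, tmp_path, lateral_curves):
        import json
        m = an.distance_matrix(lateral_curves)
        small = CurveDistanceMatrix(m.values / 10.0, m.annotator_ids, m.groups)
        vmax = batch_export({"case1": m, "case2": small}, tmp_path)
        assert vmax == pytest.approx(m.values.max())
        doc = json.loads((tmp_path / "scale.json").read_text())
        assert doc["vmax"] == pytest.approx(m.values.max())
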