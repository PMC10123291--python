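"""Geometry, shape descriptors and morphotype rules on analytic shapes."""

import math

import numpy as np
import pytest
from scipy import ndimage as ndi

from micromorph import morphometry as mm
from tests.conftest import render_random_cells


class TestMeasureCell:
    def test_analytic_disk(self, disk_mask):
        s = mm.measure_cell(disk_mask, 1.0)
        assert s.area_um2 == pytest.approx(math.pi * 50**2, rel=0.01)
        assert s.perimeter_um == pytest.approx(2 * math.pi * 50, rel=0.02)
        assert s.convex_area_um2 >= s.area_um2

    def test_analytic_square(self, square_mask):
        s = mm.measure_cell(square_mask, 1.0)
        assert s.perimeter_um == pytest.approx(400.0, rel=0.02)
        assert s.convex_area_um2 == pytest.approx(s.area_um2, rel=0.02)

    def test_cross_convex_hull(self, cross_mask):
        # hull is the octagon spanned by the bar ends: 10000 - 4*800 = 6800
        s = mm.measure_cell(cross_mask, 1.0)
        assert s.area_um2 == pytest.approx(3600.0, rel=0.01)
        assert s.convex_area_um2 == pytest.approx(6800.0, rel=0.02)

    def test_area_preserving_ellipse_invariant(self, ellipse_mask):
        s = mm.measure_cell(ellipse_mask, 1.0)
        ellipse_area = math.pi * (s.major_axis_um / 2) * (s.minor_axis_um / 2)
        assert ellipse_area == pytest.approx(s.area_um2, rel=1e-9)

    def test_pixel_size_scaling(self, cross_mask):
        s1 = mm.measure_cell(cross_mask, 1.0)
        s2 = mm.measure_cell(cross_mask, 2.0)
        assert s2.perimeter_um == pytest.approx(2 * s1.perimeter_um, rel=1e-9)
        assert s2.area_um2 == pytest.approx(4 * s1.area_um2, rel=1e-9)
        assert s2.major_axis_um == pytest.approx(2 * s1.major_axis_um, rel=1e-9)

    @pytest.mark.parametrize("bad", ["empty", "split"])
    def test_invalid_regions_raise(self, bad):
        mask = np.zeros((20, 20), dtype=bool)
        if bad == "split":
            mask[2:5, 2:5] = True
            mask[10:13, 10:13] = True
        with pytest.raises(mm.MeasurementError, match="cell 7"):
            mm.measure_cell(mask, 1.0, cell_id=7)


class TestDescriptors:
    def test_ideal_circle_closed_forms(self):
        r = 50.0
        s = mm.CellShape(1, math.pi * r**2, 2 * math.pi * r, 2 * r, 2 * r,
                         math.pi * r**2, (0, 0))
        d = mm.descriptors(s)
        assert d.circularity == pytest.approx(1.0)
        assert d.roundness == pytest.approx(1.0)
        assert d.aspect_ratio == pytest.approx(1.0)
        assert d.solidity == pytest.approx(1.0)
        assert d.complexity_index == pytest.approx(2.0 / r)

    def test_square_circularity(self, square_mask):
        d = mm.descriptors(mm.measure_cell(square_mask, 1.0))
        assert d.circularity == pytest.approx(math.pi / 4, rel=0.02)

    def test_ellipse_aspect_ratio(self, ellipse_mask):
        d = mm.descriptors(mm.measure_cell(ellipse_mask, 1.0))
        assert d.aspect_ratio == pytest.approx(3.0, abs=0.05)
        assert d.roundness == pytest.approx(1.0 / 3.0, abs=0.01)

    def test_cross_solidity(self, cross_mask):
        d = mm.descriptors(mm.measure_cell(cross_mask, 1.0))
        assert d.solidity == pytest.approx(3600.0 / 6800.0, rel=0.02)

    def test_clamping(self):
        # perimeter shorter than a circle's is geometrically impossible;
        # discretization can produce it, and circularity must clamp at 1
        s = mm.CellShape(1, 100.0, 30.0, 12.0, 100.0 * 4 / (math.pi * 12.0),
                         99.0, (0, 0))
        d = mm.descriptors(s)
        assert d.circularity == 1.0
        assert d.solidity == 1.0

    def test_reciprocity_on_rendered_cells(self):
        for _, mask in render_random_cells(150, seed=11):
            d = mm.descriptors(mm.measure_cell(mask))
            assert abs(d.roundness * d.aspect_ratio - 1.0) < 1e-9

    def test_scale_equivariance(self, cross_mask):
        d1 = mm.descriptors(mm.measure_cell(cross_mask, 1.0))
        d2 = mm.descriptors(mm.measure_cell(cross_mask, 2.0))
        assert d2.circularity == pytest.approx(d1.circularity, rel=1e-6)
        assert d2.aspect_ratio == pytest.approx(d1.aspect_ratio, rel=1e-6)
        assert d2.solidity == pytest.approx(d1.solidity, rel=1e-6)
        assert d2.complexity_index == pytest.approx(d1.complexity_index / 2, rel=1e-6)

    def test_rotation_invariance(self, ellipse_mask):
        base = mm.descriptors(mm.measure_cell(ellipse_mask, 1.0))
        yy, xx = np.mgrid[:300, :300]
        for angle in (20, 45, 73):
            t = math.radians(angle)
            u = (xx - 150) * math.cos(t) + (yy - 150) * math.sin(t)
            v = -(xx - 150) * math.sin(t) + (yy - 150) * math.cos(t)
            rot = (u / 60.0) ** 2 + (v / 20.0) ** 2 <= 1.0
            d = mm.descriptors(mm.measure_cell(rot, 1.0))
            assert d.aspect_ratio == pytest.approx(base.aspect_ratio, rel=0.02)
            assert d.circularity == pytest.approx(base.circularity, rel=0.02)
            assert d.solidity == pytest.approx(base.solidity, rel=0.02)


class TestProcessesAndClassification:
    def test_plain_disk_has_no_processes(self, disk_mask):
        n, soma_r = mm.count_processes(disk_mask, 1.0)
        assert n == 0
        assert soma_r == pytest.approx(50.0, rel=0.05)

    @pytest.mark.parametrize(
        "n_processes,aspect_ratio,expected,fallback",
        [
            (0, 1.2, mm.ROUND, False),
            (1, 3.5, mm.POLARIZED, False),
            (4, 1.5, mm.RAMIFIED, False),
            (0, 5.0, mm.ROUND, False),  # no processes wins over elongation
            (2, 1.5, mm.ROUND, True),  # outside the taxonomy -> fallback
        ],
    )
    def test_decision_rules(self, n_processes, aspect_ratio, expected, fallback):
        m = mm.classify_morphotype(aspect_ratio, n_processes)
        assert m.label == expected
        assert m.fallback is fallback

    def test_classifier_sklearn_interface(self):
        from sklearn.base import clone

        clf = mm.MorphotypeClassifier(aspect_ratio_threshold=2.5)
        assert clone(clf).get_params()["aspect_ratio_threshold"] == 2.5
        X = np.array([[1.2, 0], [3.5, 1], [1.5, 4]])
        labels = clf.fit(X).predict(X)
        assert list(labels) == [mm.ROUND, mm.POLARIZED, mm.RAMIFIED]
        assert set(clf.classes_) == set(mm.MORPHOTYPES)


class TestMeasureLabels:
    def test_border_cells_excluded(self):
        labels = np.zeros((60, 60), dtype=np.uint16)
        labels[0:12, 5:17] = 1  # touches top border
        yy, xx = np.mgrid[:60, :60]
        labels[((yy - 40) ** 2 + (xx - 40) ** 2) <= 64] = 2
        table = mm.measure_labels(labels, 1.0)
        assert list(table["cell_id"]) == [2]
        table_all = mm.measure_labels(labels, 1.0, exclude_border=False)
        assert list(table_all["cell_id"]) == [1, 2]

    def test_empty_raster_gives_empty_table(self):
        table = mm.measure_labels(np.zeros((32, 32), dtype=np.uint16))
        assert table.empty
        assert "morphotype" in table.columns
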