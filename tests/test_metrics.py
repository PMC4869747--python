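"""Fiber alignment, thickness, radial location, cell geometry."""

import math

import numpy as np
import pytest

from fibermech.background import FProteinMap
from fibermech.metrics import (
    cell_geometry,
    erosion_rings,
    fiber_alignment,
    fiber_thickness,
    radial_location,
)


class TestFiberAlignment:
    def test_identical_angles_give_zero_fa_and_that_mean(self):
        lof = np.full(500, math.radians(72.0))
        fa, theta = fiber_alignment(lof)
        assert fa == pytest.approx(0.0, abs=1e-12)
        assert math.degrees(theta) == pytest.approx(72.0)

    def test_uniform_grid_gives_one_minus_two_over_pi(self):
        lof = np.linspace(0, math.pi, 20000, endpoint=False)
        fa, _ = fiber_alignment(lof)
        assert fa == pytest.approx(1 - 2 / math.pi, abs=1e-3)

    def test_two_orthogonal_halves(self):
        lof = np.concatenate([np.zeros(500), np.full(500, math.pi / 2)])
        fa, _ = fiber_alignment(lof)
        assert fa == pytest.approx(1 - math.sqrt(2) / 2, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        lof = rng.uniform(0, math.pi, 300)
        fa1, t1 = fiber_alignment(lof)
        fa2, t2 = fiber_alignment(rng.permutation(lof))
        assert fa1 == pytest.approx(fa2)
        assert t1 == pytest.approx(t2)

    def test_axial_variant_saturates_for_uniform_angles(self):
        lof = np.linspace(0, math.pi, 20000, endpoint=False)
        fa, _ = fiber_alignment(lof, axial=True)
        assert fa == pytest.approx(1.0, abs=1e-3)

    def test_nan_entries_ignored_and_empty_rejected(self):
        lof = np.array([0.5, np.nan, 0.5])
        fa, _ = fiber_alignment(lof)
        assert fa == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            fiber_alignment(np.array([np.nan]))


class TestFiberThickness:
    def _fp(self, values, mask):
        return FProteinMap(values=values, mask=mask)

    def test_uniform_intensity(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4:6] = True
        values = np.where(mask, 7.0, 0.0)
        ft_gfp, ft = fiber_thickness(self._fp(values, mask))
        assert ft_gfp == pytest.approx(7.0)
        assert ft == pytest.approx(7.0)  # no calibration

    def test_calibration_factor_applied(self):
        mask = np.ones((4, 4), dtype=bool)
        values = np.full((4, 4), 10.0)
        _, ft = fiber_thickness(self._fp(values, mask), p_gfp=500.0,
                                p_endo=1000.0)
        assert ft == pytest.approx(30.0)

    def test_brightness_ratio_preserved(self):
        mask = np.ones((4, 4), dtype=bool)
        a = self._fp(np.full((4, 4), 10.0), mask)
        b = self._fp(np.full((4, 4), 20.0), mask)
        fta, _ = fiber_thickness(a)
        ftb, _ = fiber_thickness(b)
        assert ftb / fta == pytest.approx(2.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            fiber_thickness(self._fp(np.zeros((4, 4)), np.zeros((4, 4), bool)))


def _disk_mask(n, radius):
    rr, cc = np.mgrid[0:n, 0:n]
    return (rr - n // 2) ** 2 + (cc - n // 2) ** 2 <= radius**2


class TestRadialLocation:
    def test_rings_partition_the_mask(self):
        mask = _disk_mask(61, 25)
        rings = erosion_rings(mask)
        total = np.zeros_like(mask, dtype=int)
        for ring in rings:
            total += ring
        assert (total[mask] == 1).all()
        assert (total[~mask] == 0).all()

    def test_boundary_intensity_maps_to_periphery(self):
        mask = _disk_mask(61, 25)
        rings = erosion_rings(mask)
        values = np.where(rings[0], 5.0, 0.0)
        rl, _, _ = radial_location(values, mask)
        assert rl > 0.9

    def test_central_intensity_maps_to_center(self):
        mask = _disk_mask(61, 25)
        rings = erosion_rings(mask)
        values = np.where(rings[-1], 5.0, 0.0)
        rl, _, _ = radial_location(values, mask)
        assert rl < 0.1

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        mask = _disk_mask(61, 25)
        values = np.where(mask, rng.uniform(0, 1, mask.shape), 0.0)
        rl1, _, _ = radial_location(values, mask)
        rl2, _, _ = radial_location(values * 37.0, mask)
        assert rl1 == rl2

    def test_programmed_annulus_recovered(self, annulus_scene):
        from fibermech.pipeline import QuantifyConfig, quantify_image
        r = annulus_scene
        q = quantify_image(r.image, QuantifyConfig(pixel_size_um=0.3),
                           cell_mask=r.cell_mask)
        assert q.rl == pytest.approx(0.70, abs=0.02)

    def test_thin_mask_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, :] = True  # single erosion ring only
        with pytest.raises(ValueError):
            radial_location(np.zeros((10, 10)), mask)


class TestCellGeometry:
    def test_square_mask(self):
        mask = np.zeros((120, 120), dtype=bool)
        mask[10:110, 10:110] = True
        g = cell_geometry(mask, pixel_size_um=0.5)
        assert g.area_um2 == pytest.approx(2500.0)
        assert g.aspect_ratio == pytest.approx(1.0, abs=0.01)

    def test_elongated_ellipse_aspect_ratio(self):
        rr, cc = np.mgrid[0:120, 0:120]
        mask = ((rr - 60) / 50.0) ** 2 + ((cc - 60) / 10.0) ** 2 <= 1
        g = cell_geometry(mask, 1.0)
        assert g.aspect_ratio == pytest.approx(5.0, rel=0.05)
        assert min(g.major_axis_deg, 180 - g.major_axis_deg) < 2.0

    def test_rotated_ellipse_major_axis_direction(self):
        rr, cc = np.mgrid[0:160, 0:160].astype(float)
        t = math.radians(30.0)
        u = (rr - 80) * math.cos(t) + (cc - 80) * math.sin(t)
        v = -(rr - 80) * math.sin(t) + (cc - 80) * math.cos(t)
        mask = (u / 60.0) ** 2 + (v / 15.0) ** 2 <= 1
        g = cell_geometry(mask, 1.0)
        assert g.major_axis_deg == pytest.approx(30.0, abs=2.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            cell_geometry(np.zeros((5, 5), dtype=bool), 1.0)
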