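"""Perimeter intensity profiles and the Peripheral Distribution Index."""

import numpy as np
import pytest

from frontfish import (
    PerimeterProfile,
    PlanarImage,
    ValidationError,
    aggregate_profiles,
    compute_pdi,
    perimeter_intensity_profile,
)
from frontfish._geom import pixel_centers_um


def _uniform_image(value=7.0, shape=(100, 100), px=0.5):
    return PlanarImage(pixels=np.full(shape, value), pixel_size_um=px)


CONTOUR = np.column_stack([np.linspace(5.0, 45.0, 41), np.full(41, 25.0)])
TIP = np.array([25.0, 25.0])


def _elliptical_cell(shape=(120, 160), px=0.5, a=35.0, b=25.0, nuc_a=12.0, nuc_b=9.0):
    """Elliptical cell mask with an interior elliptical nucleus."""
    xs, ys = pixel_centers_um(shape, px)
    cx, cy = shape[1] * px / 2, shape[0] * px / 2
    cell = ((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2 <= 1.0
    nucleus = ((xs - cx) / nuc_a) ** 2 + ((ys - cy) / nuc_b) ** 2 <= 1.0
    return cell, nucleus, px


class TestPerimeterProfile:
    def test_uniform_image_gives_constant_profile(self):
        prof = perimeter_intensity_profile(_uniform_image(), CONTOUR, TIP)
        assert np.allclose(prof.intensity, 7.0)
        assert prof.arclength_um[0] == pytest.approx(-20.0)
        assert prof.arclength_um[-1] == pytest.approx(20.0)

    def test_bump_at_tip_peaks_at_zero(self):
        img = _uniform_image(0.0)
        xs, ys = pixel_centers_um(img.pixels.shape, img.pixel_size_um)
        img.pixels += 50 * np.exp(-((xs - TIP[0]) ** 2 + (ys - TIP[1]) ** 2) / (2 * 4.0**2))
        prof = perimeter_intensity_profile(img, CONTOUR, TIP)
        assert abs(prof.arclength_um[np.argmax(prof.intensity)]) <= 0.5

    def test_reversed_traversal_mirrors_profile(self):
        img = _uniform_image(0.0)
        xs, _ = pixel_centers_um(img.pixels.shape, img.pixel_size_um)
        img.pixels += xs  # linear ramp along the contour
        fwd = perimeter_intensity_profile(img, CONTOUR, TIP)
        rev = perimeter_intensity_profile(img, CONTOUR[::-1], TIP)
        assert np.allclose(fwd.arclength_um, -rev.arclength_um[::-1], atol=1e-9)
        assert np.allclose(fwd.intensity, rev.intensity[::-1], atol=1e-9)

    def test_tip_off_contour_rejected(self):
        with pytest.raises(ValidationError, match="tip"):
            perimeter_intensity_profile(_uniform_image(), CONTOUR, np.array([25.0, 10.0]))


class TestAggregateProfiles:
    def test_identical_profiles_have_zero_width_band(self):
        prof = perimeter_intensity_profile(_uniform_image(), CONTOUR, TIP)
        agg = aggregate_profiles([prof] * 5, normalize=False)
        assert np.allclose(agg.ci_high - agg.ci_low, 0.0, atol=1e-12)
        assert np.allclose(agg.mean_intensity, 7.0)

    def test_normalization_cancels_exposure_differences(self):
        base = perimeter_intensity_profile(_uniform_image(5.0), CONTOUR, TIP)
        bright = PerimeterProfile(base.arclength_um, base.intensity * 11.0)
        agg_mixed = aggregate_profiles([base, base, bright], normalize=True)
        agg_same = aggregate_profiles([base, base, base], normalize=True)
        assert np.allclose(agg_mixed.mean_intensity, agg_same.mean_intensity)

    def test_nonoverlapping_ranges_rejected(self):
        # valid profiles always share arc length 0; forge disjoint ranges to
        # exercise the defensive branch
        profiles = []
        for shift in (0.0, 100.0, 200.0):
            p = PerimeterProfile(np.array([-5.0, 0.0, 5.0]), np.ones(3))
            p.arclength_um = p.arclength_um + shift
            profiles.append(p)
        with pytest.raises(ValidationError, match="overlap"):
            aggregate_profiles(profiles)

    def test_grid_truncated_where_fewer_than_three_cells(self):
        short = PerimeterProfile(np.array([-2.0, 0.0, 2.0]), np.ones(3))
        long = PerimeterProfile(np.array([-10.0, 0.0, 10.0]), np.ones(3))
        agg = aggregate_profiles([short, short, long], normalize=False)
        assert agg.grid_um[0] >= -2.0 and agg.grid_um[-1] <= 2.0


class TestPDI:
    def test_uniform_intensity_gives_exactly_one(self):
        cell, nucleus, px = _elliptical_cell()
        signal = PlanarImage(pixels=(cell & ~nucleus) * 3.0, pixel_size_um=px)
        res = compute_pdi(signal, cell, nucleus)
        assert res.pdi == pytest.approx(1.0, abs=1e-6)

    def test_boundary_ring_signal_scores_above_one(self):
        cell, nucleus, px = _elliptical_cell()
        xs, ys = pixel_centers_um(cell.shape, px)
        cx, cy = cell.shape[1] * px / 2, cell.shape[0] * px / 2
        ring = cell & (((xs - cx) / 35.0) ** 2 + ((ys - cy) / 25.0) ** 2 >= 0.8)
        res = compute_pdi(PlanarImage(pixels=ring * 1.0, pixel_size_um=px), cell, nucleus)
        # independent discrete-moment oracle
        r2 = (xs - cx) ** 2 + (ys - cy) ** 2
        cyto = cell & ~nucleus
        expected = r2[ring & cyto].mean() / r2[cyto].mean()
        assert res.pdi == pytest.approx(expected, rel=1e-9)
        assert res.pdi > 1.0

    def test_perinuclear_signal_scores_below_one(self):
        cell, nucleus, px = _elliptical_cell()
        xs, ys = pixel_centers_um(cell.shape, px)
        cx, cy = cell.shape[1] * px / 2, cell.shape[0] * px / 2
        inner = (cell & ~nucleus) & (
            ((xs - cx) / 16.0) ** 2 + ((ys - cy) / 12.0) ** 2 <= 1.0
        )
        res = compute_pdi(PlanarImage(pixels=inner * 1.0, pixel_size_um=px), cell, nucleus)
        assert res.pdi < 1.0

    def test_invariance_to_intensity_scale_and_rigid_motion(self):
        cell, nucleus, px = _elliptical_cell()
        rng = np.random.default_rng(0)
        signal = (cell & ~nucleus) * rng.random(cell.shape)
        base = compute_pdi(PlanarImage(pixels=signal, pixel_size_um=px), cell, nucleus)
        scaled = compute_pdi(PlanarImage(pixels=signal * 40.0, pixel_size_um=px), cell, nucleus)
        assert scaled.pdi == pytest.approx(base.pdi, rel=1e-12)
        # rigid motion: translate everything by whole pixels + rotate 90 degrees
        moved = compute_pdi(
            PlanarImage(pixels=np.rot90(signal), pixel_size_um=px),
            np.rot90(cell),
            np.rot90(nucleus),
        )
        assert moved.pdi == pytest.approx(base.pdi, rel=1e-9)

    def test_pdi_increases_moving_signal_outward(self):
        cell, nucleus, px = _elliptical_cell()
        xs, ys = pixel_centers_um(cell.shape, px)
        cx, cy = cell.shape[1] * px / 2, cell.shape[0] * px / 2
        rho = np.sqrt(((xs - cx) / 35.0) ** 2 + ((ys - cy) / 25.0) ** 2)
        values = []
        for lo, hi in [(0.3, 0.5), (0.5, 0.7), (0.7, 0.9)]:  # annulus family
            annulus = cell & ~nucleus & (rho >= lo) & (rho < hi)
            res = compute_pdi(
                PlanarImage(pixels=annulus * 1.0, pixel_size_um=px), cell, nucleus
            )
            values.append(res.pdi)
        assert values[0] < values[1] < values[2]

    def test_nucleus_outside_cell_rejected(self):
        cell, nucleus, px = _elliptical_cell()
        with pytest.raises(ValidationError, match="nucleus"):
            compute_pdi(PlanarImage(pixels=cell * 1.0, pixel_size_um=px), nucleus, cell)

    def test_point_signal_accepted(self):
        cell, nucleus, px = _elliptical_cell()
        xs, ys = pixel_centers_um(cell.shape, px)
        cyto = cell & ~nucleus
        pts = np.column_stack([xs[cyto], ys[cyto]])  # every cytoplasm pixel once
        res = compute_pdi(pts, cell, nucleus, pixel_size_um=px)
        assert res.pdi == pytest.approx(1.0, abs=1e-9)
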